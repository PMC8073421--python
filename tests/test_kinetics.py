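import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grtime.io_formats import CoverageTrack, GeneAnnotation, PeakSet, PEAK_COLUMNS
from grtime.kinetics import (
    AmplitudeSeries,
    center_and_average,
    chip_mwt,
    rank_ep300_dynamic_peaks,
    signal_time_course,
)


def _flat_track(value, start=0, end=1000, chrom="c"):
    t = CoverageTrack()
    t.add_chrom(chrom, [start], [end], [value])
    return t


class TestSignalTimeCourse:
    def test_constant_field_gives_constant_series(self):
        tracks = {t: _flat_track(3.0) for t in [0.0, 1.0, 2.0]}
        s = signal_time_course(tracks, "c", 100, 200, np.array([0.0, 1.0, 2.0]))
        assert s.amplitudes.tolist() == [3.0, 3.0, 3.0]

    def test_max_vs_mean_summary(self):
        track = CoverageTrack()
        track.add_chrom("c", [0, 50], [50, 100], [2.0, 4.0])
        tracks = {0.0: track, 1.0: track}
        times = np.array([0.0, 1.0])
        s_max = signal_time_course(tracks, "c", 0, 100, times, mode="max")
        s_mean = signal_time_course(tracks, "c", 0, 100, times, mode="mean")
        assert s_max.amplitudes.tolist() == [4.0, 4.0]
        assert s_mean.amplitudes.tolist() == [3.0, 3.0]

    def test_missing_time_point_is_hard_error(self):
        tracks = {0.0: _flat_track(1.0)}
        with pytest.raises(ValueError, match="missing coverage track.*1.0"):
            signal_time_course(tracks, "c", 0, 10, np.array([0.0, 1.0]))


class TestChipMWT:
    @pytest.mark.parametrize(
        "amps,times,expected",
        [
            ([1, 1, 1, 1], [0, 1, 2, 3], 1.5),
            ([0, 0, 7, 0], [0, 1, 2, 3], 2.0),
            ([1, 2, 3, 2], [0, 0.5, 1, 2], 1.0),
        ],
    )
    def test_hand_cases(self, amps, times, expected):
        s = AmplitudeSeries("p", "f", np.array(times, float), np.array(amps, float))
        assert chip_mwt(s) == pytest.approx(expected)

    def test_all_zero_series_undefined(self):
        s = AmplitudeSeries("p", "f", np.array([0.0, 1.0]), np.zeros(2))
        assert np.isnan(chip_mwt(s))

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=8),
        st.floats(min_value=0.01, max_value=50),
        st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_and_shift_equivariance(self, amps, scale, shift):
        amps = np.asarray(amps)
        if amps.sum() == 0:
            return
        times = np.arange(len(amps), dtype=float)
        base = chip_mwt(AmplitudeSeries("p", "f", times, amps))
        scaled = chip_mwt(AmplitudeSeries("p", "f", times, scale * amps))
        shifted = chip_mwt(AmplitudeSeries("p", "f", times + shift, amps))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert shifted == pytest.approx(base + shift, rel=1e-9, abs=1e-6)


def _ranking_setup(series_values, times, amplitudes=None, starts=None):
    n = len(series_values)
    amplitudes = amplitudes or [1.0] * n
    starts = starts or [1000 * i for i in range(n)]
    rows = [
        ("c", s, s + 100, f"p{i}", a)
        for i, (s, a) in enumerate(zip(starts, amplitudes))
    ]
    peaks = PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS), factor="NR3C1")
    series = {
        f"p{i}": AmplitudeSeries(f"p{i}", "EP300", np.asarray(times, float),
                                 np.asarray(v, float), summary_mode="mean")
        for i, v in enumerate(series_values)
    }
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": "c",
        "start": [1000 * i for i in range(n)],
        "end": [1000 * i + 100 for i in range(n)],
        "strand": "+",
        "transcript_length": 100,
    }))
    return peaks, series, ann


class TestRankEP300:
    def test_hand_ordering(self):
        peaks, series, ann = _ranking_setup(
            [[0, 1, 1, 1], [0, 1, 5, 2], [0, 2, 2, 4]], [0, 0.5, 1, 2]
        )
        out = rank_ep300_dynamic_peaks(peaks, series, ann, k=3, t_min=0.5)
        assert out["peak_id"].tolist() == ["p1", "p2", "p0"]
        assert out["ep300_range"].tolist() == [4.0, 2.0, 0.0]

    def test_constant_series_scores_zero(self):
        peaks, series, ann = _ranking_setup([[3, 3, 3]], [0, 1, 2])
        out = rank_ep300_dynamic_peaks(peaks, series, ann, k=1)
        assert out.loc[0, "ep300_range"] == 0.0

    def test_top_k_selection(self):
        peaks, series, ann = _ranking_setup(
            [[0, 1, 1, 1], [0, 1, 5, 2], [0, 2, 2, 4]], [0, 0.5, 1, 2]
        )
        out = rank_ep300_dynamic_peaks(peaks, series, ann, k=2, t_min=0.5)
        assert set(out["peak_id"]) == {"p1", "p2"}

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(9)
        times = np.array([0, 0.5, 1, 2, 3, 4.0])
        vals = rng.gamma(2, 3, size=(120, len(times)))
        peaks, series, ann = _ranking_setup(list(vals), times)
        out = rank_ep300_dynamic_peaks(peaks, series, ann, k=120, t_min=0.5)
        sel = times >= 0.5
        brute = {
            f"p{i}": max(
                abs(v[a] - v[b])
                for a in np.flatnonzero(sel)
                for b in np.flatnonzero(sel)
            )
            for i, v in enumerate(vals)
        }
        got = dict(zip(out["peak_id"], out["ep300_range"]))
        assert got.keys() == brute.keys()
        for k in brute:
            assert got[k] == pytest.approx(brute[k])
        scores = out["ep300_range"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()

    def test_one_peak_per_gene_keeps_higher_amplitude(self):
        # two peaks nearest to the same gene
        rows = [("c", 0, 100, "pA", 2.0), ("c", 100, 200, "pB", 5.0)]
        peaks = PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS), factor="NR3C1")
        times = np.array([0.0, 1.0])
        series = {
            "pA": AmplitudeSeries("pA", "EP300", times, np.array([0.0, 9.0])),
            "pB": AmplitudeSeries("pB", "EP300", times, np.array([0.0, 3.0])),
        }
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["c"], "start": [100], "end": [300],
            "strand": ["+"], "transcript_length": [200],
        }))
        out = rank_ep300_dynamic_peaks(peaks, series, ann, k=2, t_min=0.0)
        assert out["peak_id"].tolist() == ["pB"]


class TestCenterAndAverage:
    def _selected(self, start, end, gene="g1"):
        return pd.DataFrame(
            [{"gene_id": gene, "chrom": "c", "start": start, "end": end}]
        )

    def test_single_gene_profile_is_own_coverage(self):
        track = _flat_track(2.0, 0, 10_000)
        tracks = {("NR3C1", 0.0): track, ("NR3C1", 1.0): track}
        out = center_and_average(
            tracks, self._selected(4_000, 4_200), {"g1": "up"}, halfwidth=100,
            bucket=10, reference_time=1.0,
        )
        sub = out[(out["factor"] == "NR3C1") & (out["time_hours"] == 0.0)]
        assert len(sub) == 20
        assert (sub["mean_signal"] == 2.0).all()

    def test_two_genes_average_constant_coverages(self):
        t = CoverageTrack()
        t.add_chrom("c", [0, 10_000], [10_000, 20_000], [2.0, 4.0])
        tracks = {("NR3C1", 1.0): t}
        selected = pd.DataFrame([
            {"gene_id": "g1", "chrom": "c", "start": 4_000, "end": 4_200},
            {"gene_id": "g2", "chrom": "c", "start": 14_000, "end": 14_200},
        ])
        out = center_and_average(
            tracks, selected, {"g1": "up", "g2": "up"}, halfwidth=100, bucket=10,
            reference_time=1.0,
        )
        assert (out["mean_signal"] == 3.0).all()

    def test_symmetric_peak_max_at_center_bucket(self, small_sim):
        tracks = small_sim["tracks"]
        truth = small_sim["chip_truth"]
        enh = truth[truth["kind"] == "enhancer"].head(5)
        selected = enh.assign(chrom="chrS")[["gene_id", "chrom", "start", "end"]]
        labels = {g: "up" for g in selected["gene_id"]}
        out = center_and_average(tracks, selected, labels, reference_time=1.0)
        prof = out[(out["factor"] == "NR3C1") & (out["time_hours"] == 1.0)]
        peak_offset = prof.loc[prof["mean_signal"].idxmax(), "offset"]
        assert abs(peak_offset) <= 10

    def test_cluster_labels_split_profiles(self):
        track = _flat_track(2.0, 0, 30_000)
        tracks = {("NR3C1", 1.0): track}
        selected = pd.DataFrame([
            {"gene_id": "g1", "chrom": "c", "start": 4_000, "end": 4_200},
            {"gene_id": "g2", "chrom": "c", "start": 14_000, "end": 14_200},
        ])
        out = center_and_average(
            tracks, selected, {"g1": "up", "g2": "random"}, halfwidth=50, bucket=10,
            reference_time=1.0,
        )
        assert set(out["cluster"]) == {"up", "random"}
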
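"""Per-peak ChIP signal kinetics.

For each gene's selected NR3C1 peak the coverage of NR3C1, EP300, H3K27ac
and H3K4me1 is summarized within the peak coordinates at every time point
(maximum coverage by default), giving an amplitude series on the time grid.
The weighted-maximum-time (MWT) of a series is the amplitude-weighted mean
of time — it locates when binding is concentrated.  EP300 temporal dynamic
range (the spread between any two time points from 30 min on) ranks peaks
for the highest-turnover analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grtime.io_formats import CoverageTrack, GeneAnnotation, PeakSet
from grtime.mapping import nearest_gene

log = logging.getLogger("grtime")

FACTORS = ["NR3C1", "EP300", "H3K27ac", "H3K4me1"]


@dataclass
class AmplitudeSeries:
    """Signal summary of one peak for one factor across the time grid."""

    peak_id: str
    factor: str
    times: np.ndarray
    amplitudes: np.ndarray
    summary_mode: str = "max"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must align")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.amplitudes < 0).any():
            raise ValueError("negative amplitude")


def signal_time_course(
    tracks: dict[float, CoverageTrack],
    chrom: str,
    start: int,
    end: int,
    times: np.ndarray,
    mode: str = "max",
    peak_id: str = "",
    factor: str = "",
) -> AmplitudeSeries:
    """Summarize coverage over [start, end) at each time point.

    ``tracks`` maps time (hours) -> CoverageTrack; every requested time
    must be present.  ``mode`` is "max" (default) or length-weighted "mean".
    """
    times = np.asarray(times, dtype=float)
    missing = [t for t in times if t not in tracks]
    if missing:
        raise ValueError(f"missing coverage track(s) for time(s) {missing}")
    if mode == "max":
        amps = [tracks[t].max(chrom, start, end) for t in times]
    elif mode == "mean":
        amps = [tracks[t].mean(chrom, start, end) for t in times]
    else:
        raise ValueError(f"unknown summary mode {mode!r}")
    return AmplitudeSeries(peak_id, factor, times, np.asarray(amps), summary_mode=mode)


def chip_mwt(series: AmplitudeSeries) -> float:
    """Amplitude-weighted mean time over the full grid, including t = 0.

    Invariant under positive scaling of amplitudes and equivariant under
    time shifts.  All-zero series are undefined: returns NaN with a log
    entry so callers can exclude the peak.
    """
    total = series.amplitudes.sum()
    if total == 0:
        log.info("chip_mwt undefined for %s/%s: all amplitudes zero",
                 series.peak_id, series.factor)
        return float("nan")
    return float((series.amplitudes * series.times).sum() / total)


def rank_ep300_dynamic_peaks(
    nr3c1_peaks: PeakSet,
    ep300_series: dict[str, AmplitudeSeries],
    ann: GeneAnnotation,
    k: int = 100,
    t_min: float = 0.5,
    tss_mode: str = "strand",
) -> pd.DataFrame:
    """Rank NR3C1 enhancer peaks by EP300 temporal dynamic range and map the
    top ``k`` to their nearest genes.

    The score of a peak is max - min of its EP300 amplitude over times
    >= ``t_min`` — the largest absolute difference between any two time
    points.  Ties break toward the larger NR3C1 peak amplitude, then the
    smaller start.  When two of the top peaks hit the same gene, the peak
    with the higher NR3C1 amplitude is retained.
    """
    rows = []
    for rec in nr3c1_peaks.df.itertuples(index=False):
        series = ep300_series.get(rec.name)
        if series is None:
            raise ValueError(f"peak {rec.name!r} has no EP300 series")
        sel = series.times >= t_min
        vals = series.amplitudes[sel]
        score = float(vals.max() - vals.min()) if len(vals) else 0.0
        rows.append((rec.name, rec.chrom, rec.start, rec.end, rec.amplitude, score))
    df = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "amplitude", "ep300_range"]
    )
    df = df.sort_values(
        ["ep300_range", "amplitude", "start"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    if k > len(df):
        log.warning("requested top %d but only %d peaks available", k, len(df))
    top = df.head(k).copy()
    top["gene_id"] = [
        nearest_gene(r.chrom, r.start, r.end, ann, tss_mode=tss_mode)
        for r in top.itertuples(index=False)
    ]
    top = top.dropna(subset=["gene_id"])
    # one peak per gene: the one with the higher NR3C1 amplitude
    dedup = (
        top.sort_values(["gene_id", "amplitude", "start"],
                        ascending=[True, False, True], kind="mergesort")
        .groupby("gene_id", sort=False)
        .head(1)
    )
    return (
        dedup.sort_values(["ep300_range", "amplitude", "start"],
                          ascending=[False, False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def center_and_average(
    tracks: dict[tuple[str, float], CoverageTrack],
    selected_peaks: pd.DataFrame,
    cluster_labels: dict[str, str],
    reference_factor: str = "NR3C1",
    reference_time: float = 1.0,
    halfwidth: int = 2_000,
    bucket: int = 10,
) -> pd.DataFrame:
    """Average bucketed coverage profiles centered on each peak's NR3C1
    summit.

    The center of a peak is the leftmost position of maximum
    ``reference_factor`` coverage within the peak at ``reference_time``.
    For every (factor, time, cluster) the mean over genes of the coverage in
    [center - halfwidth, center + halfwidth), summarized in ``bucket``-bp
    bins, is returned as a long DataFrame with columns factor, time_hours,
    cluster, offset (bucket left edge relative to the center) and
    mean_signal.  Positions beyond a chromosome edge contribute zeros.
    """
    if halfwidth % bucket != 0:
        raise ValueError("halfwidth must be a multiple of the bucket size")
    n_bins = 2 * halfwidth // bucket
    ref = tracks.get((reference_factor, reference_time))
    if ref is None:
        raise ValueError(
            f"missing reference track {reference_factor} at t={reference_time}"
        )
    centers: dict[str, tuple[str, int]] = {}
    for rec in selected_peaks.itertuples(index=False):
        c = ref.argmax(rec.chrom, int(rec.start), int(rec.end))
        centers[rec.gene_id] = (rec.chrom, c)
        if c - halfwidth < 0:
            log.info("peak for %s within %d bp of chromosome start; zero-padded",
                     rec.gene_id, halfwidth)
    offsets = -halfwidth + bucket * np.arange(n_bins)
    rows = []
    factors = sorted({f for f, _ in tracks})
    times = sorted({t for _, t in tracks})
    for factor in factors:
        for t in times:
            track = tracks.get((factor, t))
            if track is None:
                raise ValueError(f"missing coverage track {factor} at t={t}")
            sums: dict[str, np.ndarray] = {}
            counts: dict[str, int] = {}
            for gene_id, (chrom, center) in centers.items():
                cl = cluster_labels.get(gene_id)
                if cl is None:
                    continue
                prof = track.binned_means(chrom, center - halfwidth, n_bins, bucket)
                sums[cl] = sums.get(cl, 0) + prof
                counts[cl] = counts.get(cl, 0) + 1
            for cl in sorted(sums):
                mean = sums[cl] / counts[cl]
                for off, v in zip(offsets, mean):
                    rows.append((factor, t, cl, int(off), float(v)))
    return pd.DataFrame(
        rows, columns=["factor", "time_hours", "cluster", "offset", "mean_signal"]
    )
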
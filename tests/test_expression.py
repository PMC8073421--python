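import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grtime.expression import (
    differential_expression,
    expression_mwt,
    quantile_normalize,
    remove_expression_outliers,
    scale_and_classify,
    select_random_genes,
)
from grtime.io_formats import CountsTable, GeneAnnotation


def _table(cols: dict, times, reps):
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))])
    meta = pd.DataFrame({"time_hours": times, "replicate": reps}, index=list(cols))
    return CountsTable(counts.astype(float), meta)


class TestQuantileNormalize:
    def test_two_column_rank_mean_oracle(self):
        t = _table({"s1": [5, 2, 8], "s2": [4, 1, 6]}, [0, 1], [1, 1])
        out = quantile_normalize(t)
        assert out.counts["s1"].tolist() == [4.5, 1.5, 7.0]
        assert out.counts["s2"].tolist() == [4.5, 1.5, 7.0]

    def test_identical_columns_are_fixed_point(self):
        t = _table({"s1": [3, 1, 9], "s2": [3, 1, 9]}, [0, 1], [1, 1])
        out = quantile_normalize(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_sorted_columns_identical_and_idempotent(self):
        rng = np.random.default_rng(3)
        cols = {f"s{i}": rng.gamma(2, 50, 40) for i in range(5)}
        t = _table(cols, [0, 0, 1, 1, 2], [1, 2, 1, 2, 1])
        once = quantile_normalize(t)
        X = once.counts.to_numpy()
        ref = np.sort(X[:, 0])
        for j in range(X.shape[1]):
            assert np.allclose(np.sort(X[:, j]), ref)
        twice = quantile_normalize(once)
        assert np.allclose(twice.counts.to_numpy(), X)

    def test_ties_get_mean_of_reference_values(self):
        t = _table({"s1": [1, 1, 5], "s2": [2, 4, 9]}, [0, 1], [1, 1])
        out = quantile_normalize(t)
        # reference = [1.5, 2.5, 7]; tied pair shares mean(1.5, 2.5) = 2
        assert out.counts["s1"].tolist() == [2.0, 2.0, 7.0]


class TestDifferentialExpression:
    def test_flat_gene_gets_p_one(self):
        t = _table(
            {"a": [10, 1], "b": [10, 2], "c": [10, 5], "d": [10, 6]},
            [0, 0, 1, 1], [1, 2, 1, 2],
        )
        de = differential_expression(t)
        assert de.loc["g0", "F_stat"] == 0.0
        assert de.loc["g0", "p_value"] == 1.0
        assert bool(de.loc["g0", "flat"])

    def test_textbook_anova_f(self):
        # groups {1,2} vs {5,6}: SSB = 16, SSW = 1, df = (1, 2) -> F = 32
        t = _table(
            {"a": [1, 2], "b": [2, 2], "c": [5, 2], "d": [6, 2]},
            [0, 0, 1, 1], [1, 2, 1, 2],
        )
        de = differential_expression(t)
        assert de.loc["g0", "F_stat"] == pytest.approx(32.0)

    def test_bh_stepup_hand_case(self):
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests([0.01, 0.02, 0.03, 0.8], method="fdr_bh")[1]
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.8])

    def test_single_replicate_rejected(self):
        t = _table({"a": [1, 2], "b": [5, 6]}, [0, 1], [1, 1])
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(t)


class TestScaleAndClassify:
    def _run(self, profile, fdr=0.0):
        cols = {f"s{i}": [v] for i, v in enumerate(profile)}
        t = _table(cols, list(range(len(profile))), [1] * len(profile))
        de = pd.DataFrame(
            {"F_stat": [10.0], "p_value": [fdr], "fdr": [fdr], "flat": [False]},
            index=["g0"],
        )
        return scale_and_classify(t, de, threshold_main=1e-7)

    def test_flat_profile_excluded(self):
        out = self._run([10, 10, 10, 10], fdr=0.0)
        assert out.loc["g0", "cluster"] == "none"
        assert np.isnan(out.loc["g0", "z_1"])

    def test_monotone_increase_is_up_and_leveled_at_zero(self):
        out = self._run([10, 20, 30, 40], fdr=0.0)
        assert out.loc["g0", "cluster"] == "up"
        assert out.loc["g0", "z_0"] == 0.0

    def test_monotone_decrease_is_down(self):
        assert self._run([40, 30, 20, 10], fdr=0.0).loc["g0", "cluster"] == "down"

    def test_non_significant_gene_not_clustered(self):
        assert self._run([10, 20, 30, 40], fdr=0.5).loc["g0", "cluster"] == "none"

    def test_cluster_count_matches_threshold(self, small_sim):
        norm = quantile_normalize(small_sim["counts"])
        de = differential_expression(norm)
        out = scale_and_classify(norm, de, threshold_main=1e-7)
        z_defined = ~out["z_0"].isna()
        expected = int(((out["fdr"] < 1e-7) & z_defined).sum())
        assert int(out["cluster"].isin(["up", "down"]).sum()) == expected


class TestSelectRandomGenes:
    def _setup(self, n_genes=200, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n_genes)]
        counts = pd.DataFrame(
            {"s1": rng.gamma(2, 50, n_genes), "s2": rng.gamma(2, 50, n_genes)},
            index=ids,
        )
        meta = pd.DataFrame({"time_hours": [0, 1], "replicate": [1, 1]},
                            index=["s1", "s2"])
        table = CountsTable(counts, meta)
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ids,
            "chrom": "c",
            "start": 1000 * np.arange(n_genes),
            "end": 1000 * np.arange(n_genes) + 500,
            "strand": "+",
            "transcript_length": rng.integers(500, 10_000, n_genes),
        }))
        return table, ann

    def _regulated(self, table, gene_ids):
        reg = pd.DataFrame(
            {"fdr": 1.0, "cluster": "none"}, index=table.counts.index
        )
        reg.loc[gene_ids, "cluster"] = "up"
        reg.loc[gene_ids, "fdr"] = 0.0
        return reg

    def test_deterministic_given_seed(self):
        table, ann = self._setup()
        reg = self._regulated(table, [f"g{i}" for i in range(20)])
        a = select_random_genes(table, ann, reg, n=30, seed=5)
        b = select_random_genes(table, ann, reg, n=30, seed=5)
        assert a == b

    def test_disjoint_from_regulated(self):
        table, ann = self._setup()
        reg_ids = [f"g{i}" for i in range(20)]
        reg = self._regulated(table, reg_ids)
        chosen = select_random_genes(table, ann, reg, n=30, seed=5)
        assert not set(chosen) & set(reg_ids)
        assert len(chosen) == 30

    def test_matches_expression_stratum_of_regulated_set(self):
        table, ann = self._setup(n_genes=400, seed=1)
        mean_expr = table.counts.mean(axis=1)
        top_decile = mean_expr.rank(method="first") > 0.9 * len(mean_expr)
        reg_ids = list(mean_expr.index[top_decile][:20])
        reg = self._regulated(table, reg_ids)
        chosen = select_random_genes(table, ann, reg, n=20, seed=2)
        frac_top = np.mean([top_decile[g] for g in chosen])
        assert frac_top >= 0.9

    def test_zero_request_gives_empty(self):
        table, ann = self._setup()
        reg = self._regulated(table, ["g0"])
        assert select_random_genes(table, ann, reg, n=0, seed=1) == []


class TestOutlierRemoval:
    def test_tukey_fence_drops_extreme(self):
        out = remove_expression_outliers({0.0: np.array([10.0, 11, 12, 100])})
        assert out[0.0].tolist() == [10.0, 11.0, 12.0]

    def test_too_few_values_pass_through(self):
        out = remove_expression_outliers({0.0: np.array([10.0, 11.0])})
        assert out[0.0].tolist() == [10.0, 11.0]

    def test_all_equal_unchanged(self):
        out = remove_expression_outliers({0.0: np.array([5.0, 5.0, 5.0, 5.0])})
        assert len(out[0.0]) == 4


class TestExpressionMWT:
    @pytest.mark.parametrize(
        "profile,times,direction,expected",
        [
            ([10, 10, 20, 40], [0, 1, 2, 3], "up", 8 / 3),
            ([0, 0, 10, 10], [0, 1, 2, 3], "up", 2.0),
            ([0, 10, 20, 30], [0, 1, 2, 3], "up", 2.0),
            ([30, 20, 10, 0], [0, 1, 2, 3], "down", 2.0),
        ],
    )
    def test_hand_cases(self, profile, times, direction, expected):
        got = expression_mwt(np.array(profile, float), np.array(times, float), direction)
        assert got == pytest.approx(expected)

    def test_all_zero_weights_undefined(self):
        got = expression_mwt(np.array([30.0, 20, 10]), np.array([0.0, 1, 2]), "up")
        assert np.isnan(got)

    @given(
        st.lists(st.floats(min_value=0, max_value=1e4), min_size=3, max_size=8),
        st.floats(min_value=0.1, max_value=100),
        st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_affine_invariance(self, profile, a, b):
        profile = np.asarray(profile)
        times = np.arange(len(profile), dtype=float)
        mwt = expression_mwt(profile, times, "up")
        if np.isnan(mwt):
            return
        assert times[1] <= mwt <= times[-1]
        scaled = expression_mwt(a * profile + b, times, "up")
        assert scaled == pytest.approx(mwt, rel=1e-9, abs=1e-9)
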
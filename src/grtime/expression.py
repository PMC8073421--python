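"""Expression side of the time course: normalization, regulated-gene
detection, profile scaling, control-gene matching and the expression MWT.

The weighted-maximum-time (MWT) of expression locates when transcript
abundance changes fastest: forward differences of the replicate-averaged
profile serve as weights on the time grid.  For an upregulated gene only
upward differences carry weight (and symmetrically for downregulated
genes), so post-peak decay does not drag the statistic late; absolute
weights are available via ``weights="absolute"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from grtime.io_formats import CountsTable, GeneAnnotation

log = logging.getLogger("grtime")

CLUSTER_UP = "up"
CLUSTER_DOWN = "down"
CLUSTER_RANDOM = "random"
CLUSTER_NONE = "none"


def quantile_normalize(counts: CountsTable) -> CountsTable:
    """Quantile-normalize samples so every column shares one distribution.

    The reference distribution is the across-sample mean of the sorted
    columns.  Ties within a column receive the mean of the reference values
    at the tied ranks, so the map is well defined and idempotent.
    """
    X = counts.counts.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        log.warning("quantile_normalize with a single sample is the identity")
        return CountsTable(counts.counts.copy(), counts.sample_meta.copy())
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # ties: average the reference values over each run of equal inputs
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        for grp in np.split(order, boundaries):
            if len(grp) > 1:
                assigned[grp] = assigned[grp].mean()
        out[:, j] = assigned
    normed = pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)
    return CountsTable(normed, counts.sample_meta.copy())


def differential_expression(norm: CountsTable) -> pd.DataFrame:
    """One-way ANOVA of expression across time points, per gene, with
    Benjamini-Hochberg FDR across genes.

    Returns a DataFrame indexed by gene_id with columns F_stat, p_value,
    fdr, flat (True for zero-variance genes, which get p = 1 by convention).
    """
    times = norm.times
    groups = [norm.counts[norm.samples_at(t)].to_numpy(dtype=float) for t in times]
    if min(g.shape[1] for g in groups) < 2:
        raise ValueError("need >= 2 replicates per time point for a valid F test")
    X = np.concatenate(groups, axis=1)
    flat = X.var(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = stats.f_oneway(*groups, axis=1)
    F = np.where(flat | ~np.isfinite(F), np.where(flat, 0.0, np.inf), F)
    p = np.where(flat, 1.0, p)
    p = np.where(np.isfinite(p), p, 0.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    if flat.any():
        log.info("%d zero-variance genes assigned p = 1", int(flat.sum()))
    return pd.DataFrame(
        {"F_stat": F, "p_value": p, "fdr": fdr, "flat": flat},
        index=norm.counts.index,
    )


def scale_and_classify(
    norm: CountsTable,
    de: pd.DataFrame,
    threshold_main: float = 1e-7,
) -> pd.DataFrame:
    """Scale replicate-averaged profiles (z-score over time, leveled to 0 at
    the baseline time point) and call regulated genes up or down.

    Only genes with fdr < ``threshold_main`` enter the clusters; the call is
    the sign of the summed leveled profile over t > 0.  Genes with a
    zero-variance profile have no z-score and are excluded from clustering.
    Returns ``de`` augmented with a ``cluster`` column and one ``z_<t>``
    column per time point.
    """
    prof = norm.mean_by_time()
    times = prof.columns.to_numpy(dtype=float)
    vals = prof.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    mean = vals.mean(axis=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean[:, None]) / sd[:, None]
    z = z - z[:, [0]]  # leveled to 0 at the baseline time point
    z[degenerate] = np.nan
    if degenerate.any():
        log.info("%d zero-variance profiles excluded from clustering", int(degenerate.sum()))
    out = de.copy()
    significant = (out["fdr"] < threshold_main).to_numpy() & ~degenerate
    post = z[:, times > times.min()]
    cluster = np.where(post.sum(axis=1) > 0, CLUSTER_UP, CLUSTER_DOWN)
    out["cluster"] = np.where(significant, cluster, CLUSTER_NONE)
    for i, t in enumerate(times):
        out[f"z_{t:g}"] = z[:, i]
    return out


def select_random_genes(
    all_counts: CountsTable,
    ann: GeneAnnotation,
    regulated: pd.DataFrame,
    n: int,
    seed: int,
    n_strata: int = 10,
) -> list[str]:
    """Pick ``n`` non-regulated control genes matched to the regulated set.

    Matching is stratified jointly on deciles of mean normalized expression
    and deciles of transcript length (computed over all annotated genes);
    the control draw reproduces the regulated set's stratum proportions.
    Strata short of candidates are topped up from the nearest stratum.
    Deterministic for a fixed seed.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    mean_expr = all_counts.counts.mean(axis=1)
    lengths = ann.df.set_index("gene_id")["transcript_length"]
    genes = mean_expr.index.intersection(lengths.index)
    mean_expr, lengths = mean_expr.loc[genes], lengths.loc[genes]
    e_dec = pd.qcut(mean_expr.rank(method="first"), n_strata, labels=False)
    l_dec = pd.qcut(lengths.rank(method="first"), n_strata, labels=False)
    strata = pd.DataFrame({"e": e_dec, "l": l_dec}, index=genes)

    reg_ids = regulated.index[regulated["cluster"].isin([CLUSTER_UP, CLUSTER_DOWN])]
    reg_ids = reg_ids.intersection(genes)
    eligible = strata.drop(index=reg_ids)
    if n > len(eligible):
        raise ValueError(f"requested {n} control genes but only {len(eligible)} eligible")

    reg_strata = strata.loc[reg_ids]
    reg_counts = reg_strata.groupby(["e", "l"]).size()
    raw = reg_counts / reg_counts.sum() * n
    quota = raw.astype(int)  # largest-remainder apportionment
    short = n - int(quota.sum())
    if short > 0:
        frac_order = (raw - quota).sort_values(ascending=False).index
        for key in frac_order[:short]:
            quota[key] += 1

    pool = {k: list(g.index) for k, g in eligible.groupby(["e", "l"])}
    chosen: list[str] = []
    shortfalls: list[tuple[tuple[int, int], int]] = []
    for key, want in quota.items():
        cand = pool.get(key, [])
        take = min(want, len(cand))
        if take:
            picked = rng.choice(sorted(cand), size=take, replace=False)
            chosen.extend(picked)
            pool[key] = [g for g in cand if g not in set(picked)]
        if take < want:
            shortfalls.append((key, want - take))
    for (e0, l0), short in shortfalls:
        log.info("stratum (%s,%s) short by %d; filling from nearest", e0, l0, short)
        # expression-level closeness outranks transcript-length closeness
        others = sorted(
            (abs(e - e0), abs(l - l0), e, l)
            for (e, l), cand in pool.items()
            if cand
        )
        for _, _, e, l in others:
            cand = pool[(e, l)]
            take = min(short, len(cand))
            picked = rng.choice(sorted(cand), size=take, replace=False)
            chosen.extend(picked)
            pool[(e, l)] = [g for g in cand if g not in set(picked)]
            short -= take
            if short == 0:
                break
    return sorted(chosen)


def remove_expression_outliers(values_by_time: dict[float, np.ndarray]) -> dict[float, np.ndarray]:
    """Drop per-time-point replicate values outside the Tukey fences
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Quartiles use linear interpolation
    (type 7).  Time points with fewer than 3 values pass through unchanged.
    """
    cleaned = {}
    for t, vals in values_by_time.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            cleaned[t] = vals
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
        cleaned[t] = vals[keep]
    return cleaned


def expression_mwt(
    profile: np.ndarray,
    times: np.ndarray,
    direction: str,
    weights: str = "clamped",
) -> float:
    """Weighted maximum time of expression change.

    Forward differences d_i = x(t_i) - x(t_{i-1}) are attributed to the
    later time t_i.  With ``weights="clamped"`` (default) only differences
    in the cluster's direction count: w_i = max(d_i, 0) for up, max(-d_i, 0)
    for down; ``weights="absolute"`` uses |d_i|.  Returns NaN (with a log
    entry) when all weights vanish.
    """
    profile = np.asarray(profile, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(profile) != len(times) or len(times) < 2:
        raise ValueError("profile and times must align with >= 2 time points")
    d = np.diff(profile)
    if weights == "absolute":
        w = np.abs(d)
    elif weights == "clamped":
        if direction == CLUSTER_UP:
            w = np.clip(d, 0.0, None)
        elif direction == CLUSTER_DOWN:
            w = np.clip(-d, 0.0, None)
        else:
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    else:
        raise ValueError(f"unknown weights mode {weights!r}")
    total = w.sum()
    if total == 0:
        log.info("expression_mwt undefined: all derivative weights zero")
        return float("nan")
    return float((w * times[1:]).sum() / total)
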
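"""Group-level statistics for the time-course comparisons.

Covers the two-way (time x regulation cluster) interaction ANOVA on peak
amplitudes, post hoc ratio t-tests against the baseline time point, one- or
two-way ANOVA on MWT distributions with Bonferroni pairwise tests, and the
cubic polynomial fits used for trend lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger("grtime")


@dataclass
class StatReport:
    test_name: str
    F: float
    p: float
    df: tuple[int, int]
    posthoc: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["comparison", "p_raw", "p_adjusted"]
        )
    )

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


def twoway_anova_time_cluster(data: pd.DataFrame) -> StatReport:
    """Interaction F test of a two-factor (time x cluster) layout.

    ``data`` has columns value, time_hours, cluster with >= 2 observations
    per cell.  Uses type-II sums of squares, which tolerate the unbalanced
    gene counts across clusters.  A layout with no residual and no
    between-cell variation gets F = 0, p = 1 by convention.
    """
    cells = data.groupby(["time_hours", "cluster"]).size()
    n_times = data["time_hours"].nunique()
    n_clusters = data["cluster"].nunique()
    if n_times < 2 or n_clusters < 2:
        raise ValueError("need >= 2 time levels and >= 2 clusters")
    expected = n_times * n_clusters
    if len(cells) < expected:
        have = set(cells.index)
        missing = [
            (t, c)
            for t in data["time_hours"].unique()
            for c in data["cluster"].unique()
            if (t, c) not in have
        ]
        raise ValueError(f"empty cell(s): {missing}")
    if (cells < 2).any():
        bad = cells.index[cells < 2][0]
        raise ValueError(f"cell {bad} has < 2 observations")
    df_int = (n_times - 1) * (n_clusters - 1)
    df_resid = len(data) - expected
    if data["value"].nunique() == 1:
        return StatReport("twoway_time_x_cluster", 0.0, 1.0, (df_int, df_resid))
    d = data.rename(columns={"value": "y"})
    model = smf.ols("y ~ C(time_hours) * C(cluster)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(time_hours):C(cluster)"]
    F = float(row["F"])
    p = float(row["PR(>F)"])
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    return StatReport("twoway_time_x_cluster", F, p, (df_int, int(model.df_resid)))


def posthoc_baseline_ttests(
    ratios: pd.DataFrame,
    baseline_time: float = 0.0,
    equal_var: bool = False,
) -> StatReport:
    """Per cluster and time point, a two-sample t-test of amplitude ratios
    against the baseline time point.

    ``ratios`` has columns ratio, time_hours, cluster where ratio is a
    gene's amplitude divided by the mean random-cluster amplitude at the
    same time.  Welch's test by default.  Zero-variance comparisons are
    reported with p = 1 and flagged in the comparison label.
    """
    rows = []
    for cluster, sub in ratios.groupby("cluster", sort=True):
        base = sub.loc[sub["time_hours"] == baseline_time, "ratio"].to_numpy()
        if len(base) < 2:
            log.info("cluster %s has < 2 baseline ratios; skipped", cluster)
            continue
        for t in sorted(sub["time_hours"].unique()):
            if t == baseline_time:
                continue
            vals = sub.loc[sub["time_hours"] == t, "ratio"].to_numpy()
            if len(vals) < 2:
                log.info("cluster %s t=%g has < 2 ratios; skipped", cluster, t)
                continue
            label = f"{cluster}:t{t:g}_vs_t{baseline_time:g}"
            if np.var(vals) == 0 and np.var(base) == 0:
                rows.append((label + "[flat]", 1.0, 1.0))
                continue
            _, p = stats.ttest_ind(vals, base, equal_var=equal_var)
            rows.append((label, float(p), float(p)))
    posthoc = pd.DataFrame(rows, columns=["comparison", "p_raw", "p_adjusted"])
    return StatReport("posthoc_vs_baseline", float("nan"), float("nan"), (0, 0), posthoc)


def mwt_group_tests(
    mwt: pd.DataFrame,
    design: str = "oneway",
    equal_var: bool = False,
) -> StatReport:
    """Compare MWT distributions across factor groups.

    ``mwt`` has columns value, factor and, for ``design="twoway"``, a
    ``geneset`` column.  One-way: ANOVA across factors, then pairwise
    t-tests of expression vs every other factor and NR3C1 vs every other
    factor, Bonferroni-multiplied by the number of tests performed.
    Two-way: factor x geneset ANOVA (type II) plus the same pairwise family
    within each gene set.
    """
    groups = {
        f: sub["value"].dropna().to_numpy()
        for f, sub in mwt.groupby("factor", sort=True)
    }
    for f in list(groups):
        if len(groups[f]) < 2:
            log.info("factor %s has < 2 MWT values; excluded", f)
            del groups[f]
    if len(groups) < 2:
        raise ValueError("need MWTs for >= 2 factors")

    def pairwise(gs: dict[str, np.ndarray], prefix: str = "") -> list[tuple[str, float]]:
        pairs = []
        seen = set()
        for anchor in ("expression", "NR3C1"):
            if anchor not in gs:
                continue
            for other in sorted(gs):
                if other == anchor or frozenset((anchor, other)) in seen:
                    continue
                seen.add(frozenset((anchor, other)))
                _, p = stats.ttest_ind(gs[anchor], gs[other], equal_var=equal_var)
                pairs.append((f"{prefix}{anchor}_vs_{other}", float(p)))
        return pairs

    if design == "oneway":
        F, p = stats.f_oneway(*groups.values())
        dfn = len(groups) - 1
        dfd = sum(len(g) for g in groups.values()) - len(groups)
        raw = pairwise(groups)
    elif design == "twoway":
        d = mwt.dropna(subset=["value"]).rename(columns={"value": "y"})
        model = smf.ols("y ~ C(factor) * C(geneset)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        row = table.loc["C(factor):C(geneset)"]
        F, p = float(row["F"]), float(row["PR(>F)"])
        dfn, dfd = int(row["df"]), int(model.df_resid)
        raw = []
        for gs_name, sub in d.groupby("geneset", sort=True):
            gs = {
                f: s["y"].to_numpy()
                for f, s in sub.groupby("factor", sort=True)
                if len(s) >= 2
            }
            raw.extend(pairwise(gs, prefix=f"{gs_name}:"))
    else:
        raise ValueError(f"unknown design {design!r}")
    m = len(raw)
    posthoc = pd.DataFrame(
        [(label, praw, min(1.0, praw * m)) for label, praw in raw],
        columns=["comparison", "p_raw", "p_adjusted"],
    )
    return StatReport(f"mwt_{design}", float(F), float(p), (dfn, dfd), posthoc)


def poly3_fit(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Least-squares cubic fit; returns coefficients (c0, c1, c2, c3) in
    ascending degree.  Requires >= 4 distinct time points."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(times)) < 4:
        raise ValueError("poly3_fit needs >= 4 distinct times")
    return np.polynomial.polynomial.polyfit(times, values, 3)


def poly3_expression_derivative_fit(
    times: np.ndarray, profile: np.ndarray, scale: float = 100.0
) -> np.ndarray:
    """Cubic fit to the forward differences of an expression profile,
    scaled (x100 by default) so the trend co-plots with amplitude panels.
    Differences are attributed to the later time point."""
    times = np.asarray(times, dtype=float)
    d = np.diff(np.asarray(profile, dtype=float)) * scale
    return poly3_fit(times[1:], d)
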
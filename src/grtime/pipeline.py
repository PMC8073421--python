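"""End-to-end orchestration of the time-course analysis.

The pipeline runs: quantile normalization -> per-gene ANOVA + FDR ->
profile scaling and up/down classification -> matched random control set ->
NR3C1 peak-to-gene assignment at the reference time -> strongest enhancer
peak per gene -> per-factor amplitude time courses and MWTs -> expression
MWT -> EP300 dynamic-range top-K -> group statistics.  ``run_pipeline``
works on in-memory objects; ``run_all`` wraps it with file IO, a YAML
config and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from grtime import expression as expr
from grtime import group_stats as gs
from grtime import kinetics as kin
from grtime import mapping as mp
from grtime.io_formats import (
    CountsTable,
    CoverageTrack,
    GeneAnnotation,
    PeakSet,
    read_annotation,
    read_counts,
    read_coverage,
    read_narrowpeak,
)

log = logging.getLogger("grtime")


@dataclass
class PipelineConfig:
    """All thresholds and switches of the analysis, with the study's
    defaults: main FDR 1e-7 (secondary 0.1 for the EP300 top-K overlap),
    +/-100 kb TSS window with a +/-2 kb promoter core, the 1 h reference
    time for peak selection, top 100 EP300-dynamic peaks scored from 0.5 h
    on."""

    counts_path: str = ""
    meta_path: str = ""
    annotation_path: str = ""
    nr3c1_peaks_path: str = ""
    tracks: dict = field(default_factory=dict)  # factor -> {time: path}
    out_dir: str = "results"
    fdr_main: float = 1e-7
    fdr_secondary: float = 0.1
    window: int = 100_000
    promoter: int = 2_000
    reference_time: float = 1.0
    ep300_k: int = 100
    ep300_t_min: float = 0.5
    seed: int = 0
    n_random: int | None = None
    mwt_weights: str = "clamped"
    tss_mode: str = "strand"
    summary_mode: str = "max"

    def __post_init__(self) -> None:
        for name, v in [("fdr_main", self.fdr_main), ("fdr_secondary", self.fdr_secondary)]:
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.window > self.promoter > 0:
            raise ValueError("need window > promoter > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    normalized: CountsTable
    regulated: pd.DataFrame          # DE table with clusters and z profiles
    random_genes: list[str]
    assignments: pd.DataFrame        # peak-to-gene table at the reference time
    selected_peaks: pd.DataFrame     # strongest enhancer peak per gene
    series: pd.DataFrame             # long: gene_id, factor, time_hours, amplitude
    mwt: pd.DataFrame                # gene_id x (expression + factors) in hours
    ep300_top: pd.DataFrame
    stats: gs.StatReport
    counts_log: dict = field(default_factory=dict)


def _cluster_labels(regulated: pd.DataFrame, random_genes: list[str]) -> dict[str, str]:
    labels = {
        g: c
        for g, c in regulated["cluster"].items()
        if c in (expr.CLUSTER_UP, expr.CLUSTER_DOWN)
    }
    labels.update({g: expr.CLUSTER_RANDOM for g in random_genes})
    return labels


def run_pipeline(
    counts: CountsTable,
    ann: GeneAnnotation,
    nr3c1_peaks: PeakSet,
    tracks: dict[tuple[str, float], CoverageTrack],
    cfg: PipelineConfig,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``nr3c1_peaks`` are the (replicate-merged) NR3C1 peaks at the reference
    time point; ``tracks`` maps (factor, time_hours) to a coverage track.
    """
    counts_log: dict[str, int] = {}
    times = counts.times

    norm = expr.quantile_normalize(counts)
    de = expr.differential_expression(norm)
    regulated = expr.scale_and_classify(norm, de, threshold_main=cfg.fdr_main)
    clusters = regulated["cluster"]
    counts_log["genes_total"] = len(regulated)
    counts_log["genes_up"] = int((clusters == expr.CLUSTER_UP).sum())
    counts_log["genes_down"] = int((clusters == expr.CLUSTER_DOWN).sum())
    n_regulated = counts_log["genes_up"] + counts_log["genes_down"]
    n_random = cfg.n_random if cfg.n_random is not None else n_regulated
    random_genes = expr.select_random_genes(
        norm, ann, regulated, n=min(n_random, len(regulated) - n_regulated),
        seed=cfg.seed,
    )
    counts_log["genes_random"] = len(random_genes)

    assignments = mp.assign_peaks(
        nr3c1_peaks, ann, window=cfg.window, promoter=cfg.promoter,
        tss_mode=cfg.tss_mode,
    )
    labels = _cluster_labels(regulated, random_genes)
    in_scope = assignments["gene_id"].isin(labels)
    selected = mp.strongest_enhancer_peak(assignments[in_scope])
    counts_log["peaks_assigned"] = len(assignments)
    counts_log["genes_with_enhancer_peak"] = len(selected)

    factor_times = sorted({t for _, t in tracks})
    chip_rows, mwt_rows = [], []
    for rec in selected.itertuples(index=False):
        entry = {"gene_id": rec.gene_id}
        for factor in kin.FACTORS:
            per_time = {t: tracks[(factor, t)] for t in factor_times}
            series = kin.signal_time_course(
                per_time, rec.chrom, int(rec.start), int(rec.end),
                np.asarray(factor_times), mode=cfg.summary_mode,
                peak_id=rec.gene_id, factor=factor,
            )
            entry[factor] = kin.chip_mwt(series)
            for t, a in zip(series.times, series.amplitudes):
                chip_rows.append((rec.gene_id, factor, float(t), float(a)))
        mwt_rows.append(entry)
    series_df = pd.DataFrame(
        chip_rows, columns=["gene_id", "factor", "time_hours", "amplitude"]
    )
    mwt_df = pd.DataFrame(mwt_rows).set_index("gene_id") if mwt_rows else pd.DataFrame()

    # expression MWT on outlier-cleaned, replicate-averaged normalized counts
    expr_mwt = {}
    for gid in mwt_df.index if not mwt_df.empty else []:
        direction = labels.get(gid)
        if direction not in (expr.CLUSTER_UP, expr.CLUSTER_DOWN):
            continue
        by_time = {
            t: norm.counts.loc[gid, norm.samples_at(t)].to_numpy() for t in times
        }
        cleaned = expr.remove_expression_outliers(by_time)
        profile = np.array([cleaned[t].mean() for t in times])
        expr_mwt[gid] = expr.expression_mwt(
            profile, times, direction=direction, weights=cfg.mwt_weights
        )
    if not mwt_df.empty:
        mwt_df["expression"] = pd.Series(expr_mwt)
    counts_log["genes_with_mwt"] = int(len(mwt_df))

    # EP300 dynamic-range ranking over all enhancer NR3C1 peaks
    enh = assignments[assignments["region_class"] == mp.REGION_ENHANCER]
    uniq = enh.drop_duplicates(subset=["chrom", "start", "end"]).copy()
    uniq["name"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(uniq["chrom"], uniq["start"], uniq["end"])
    ]
    uniq_ps = PeakSet(
        uniq[["chrom", "start", "end", "name", "amplitude"]],
        factor="NR3C1", time_hours=cfg.reference_time,
    )
    ep300_tracks = {t: tracks[("EP300", t)] for t in factor_times}
    ep300_series = {
        rec.name: kin.signal_time_course(
            ep300_tracks, rec.chrom, int(rec.start), int(rec.end),
            np.asarray(factor_times), mode="mean",
            peak_id=rec.name, factor="EP300",
        )
        for rec in uniq_ps.df.itertuples(index=False)
    }
    ep300_top = kin.rank_ep300_dynamic_peaks(
        uniq_ps, ep300_series, ann, k=cfg.ep300_k, t_min=cfg.ep300_t_min,
        tss_mode=cfg.tss_mode,
    )
    counts_log["ep300_top_genes"] = len(ep300_top)

    # one-way ANOVA across MWT groups for upregulated genes
    stats_report = None
    if not mwt_df.empty:
        up_ids = [g for g, c in labels.items() if c == expr.CLUSTER_UP]
        up_mwt = mwt_df.loc[mwt_df.index.intersection(up_ids)]
        long = up_mwt.melt(var_name="factor", value_name="value").dropna()
        if long["factor"].nunique() >= 2:
            stats_report = gs.mwt_group_tests(long, design="oneway")
    return PipelineResult(
        normalized=norm,
        regulated=regulated,
        random_genes=random_genes,
        assignments=assignments,
        selected_peaks=selected,
        series=series_df,
        mwt=mwt_df,
        ep300_top=ep300_top,
        stats=stats_report,
        counts_log=counts_log,
    )


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """Load every input from ``cfg`` paths, run the pipeline, and write the
    result tables plus a manifest to ``cfg.out_dir``."""
    for name in ("counts_path", "meta_path", "annotation_path", "nr3c1_peaks_path"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{name} missing or does not exist: {p!r}")
    counts = read_counts(cfg.counts_path, cfg.meta_path)
    ann = read_annotation(cfg.annotation_path)
    peaks = read_narrowpeak(
        cfg.nr3c1_peaks_path, factor="NR3C1", time_hours=cfg.reference_time
    )
    tracks: dict[tuple[str, float], CoverageTrack] = {}
    for factor, by_time in cfg.tracks.items():
        for t, path in by_time.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"coverage track missing for {factor} at t={t}: {path}"
                )
            tracks[(factor, float(t))] = read_coverage(
                path, factor=factor, time_hours=float(t)
            )
    result = run_pipeline(counts, ann, peaks, tracks, cfg)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.regulated.sort_index().to_csv(out / "regulated.tsv", sep="\t",
                                         index_label="gene_id")
    pd.Series(sorted(result.random_genes), name="gene_id").to_csv(
        out / "random_genes.tsv", sep="\t", index=False
    )
    result.assignments.sort_values(["gene_id", "start"]).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    result.selected_peaks.sort_values("gene_id").to_csv(
        out / "selected_peaks.tsv", sep="\t", index=False
    )
    result.series.to_csv(out / "series.tsv", sep="\t", index=False)
    result.mwt.sort_index().to_csv(out / "mwt.tsv", sep="\t", index_label="gene_id")
    result.ep300_top.to_csv(out / "ep300_top.tsv", sep="\t", index=False)
    if result.stats is not None:
        result.stats.posthoc.to_csv(out / "mwt_posthoc.tsv", sep="\t", index=False)
    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stage_counts": result.counts_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", result.counts_log)
    return result
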
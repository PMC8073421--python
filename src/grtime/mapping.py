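"""Peak-to-gene assignment around TSSs.

A peak belongs to a gene when its midpoint lies within +/- ``window`` bp of
the gene's TSS; the +/- ``promoter`` bp core around the TSS is classed as
promoter and everything else in the window as enhancer, so the two classes
partition the window exactly.  One peak may serve several genes; uniqueness
is enforced only downstream where required (the EP300 top-K path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from grtime.io_formats import GeneAnnotation, PeakSet, PEAK_COLUMNS

log = logging.getLogger("grtime")

REGION_PROMOTER = "promoter"
REGION_ENHANCER = "enhancer"

ASSIGNMENT_COLUMNS = [
    "gene_id", "chrom", "start", "end", "amplitude",
    "region_class", "distance_to_tss",
]


def intersect_replicates(peaksets: list[PeakSet]) -> PeakSet:
    """Base-wise intersection of replicate peak sets.

    Output intervals are the maximal regions covered by a peak in every
    replicate; each carries the mean of the contributing replicate
    amplitudes.  A single replicate is returned unchanged.  Commutative and
    associative over replicate order (assuming non-overlapping peaks within
    each replicate).
    """
    if not peaksets:
        raise ValueError("need at least one replicate")
    factor, time_hours = peaksets[0].factor, peaksets[0].time_hours
    if len(peaksets) == 1:
        return PeakSet(peaksets[0].df.copy(), factor=factor, time_hours=time_hours)

    def to_records(ps: PeakSet):
        return [
            (r.chrom, int(r.start), int(r.end), [float(r.amplitude)])
            for r in ps.df.itertuples(index=False)
        ]

    current = to_records(peaksets[0])
    for nxt in peaksets[1:]:
        other = to_records(nxt)
        merged = []
        for chrom in sorted({c for c, *_ in current} | {c for c, *_ in other}):
            a = [r for r in current if r[0] == chrom]
            b = [r for r in other if r[0] == chrom]
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][1], b[j][1])
                e = min(a[i][2], b[j][2])
                if s < e:
                    merged.append((chrom, s, e, a[i][3] + b[j][3]))
                if a[i][2] <= b[j][2]:
                    i += 1
                else:
                    j += 1
        current = merged
    if not current:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS), factor=factor, time_hours=time_hours)
    df = pd.DataFrame(
        [
            (c, s, e, f"{c}:{s}-{e}", float(np.mean(amps)))
            for c, s, e, amps in current
        ],
        columns=PEAK_COLUMNS,
    )
    return PeakSet(df, factor=factor, time_hours=time_hours)


def assign_peaks(
    peaks: PeakSet,
    ann: GeneAnnotation,
    window: int = 100_000,
    promoter: int = 2_000,
    tss_mode: str = "strand",
) -> pd.DataFrame:
    """Assign peaks to every gene whose TSS lies within ``window`` bp of the
    peak midpoint.

    ``distance_to_tss`` is signed along the gene: negative means upstream of
    the TSS on the gene's strand.  ``region_class`` is promoter when
    |distance| <= ``promoter``, else enhancer.
    """
    tss = ann.tss(mode=tss_mode)
    gene_chrom = pd.Series(ann.df["chrom"].to_numpy(), index=ann.df["gene_id"].to_numpy())
    gene_strand = pd.Series(ann.df["strand"].to_numpy(), index=ann.df["gene_id"].to_numpy())
    rows = []
    for chrom, sub in peaks.df.groupby("chrom", sort=True):
        ids = gene_chrom.index[gene_chrom == chrom].to_numpy()
        if len(ids) == 0:
            continue
        pos = tss.loc[ids].to_numpy(dtype=float)
        order = np.argsort(pos, kind="mergesort")
        pos, ids = pos[order], ids[order]
        sign = np.where(gene_strand.loc[ids].to_numpy() == "+", 1.0, -1.0)
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        lo = np.searchsorted(pos, mids - window, side="left")
        hi = np.searchsorted(pos, mids + window, side="right")
        for (_, peak), l, h, mid in zip(sub.iterrows(), lo, hi, mids):
            for k in range(l, h):
                d = (mid - pos[k]) * sign[k]
                rows.append(
                    (
                        ids[k], chrom, int(peak["start"]), int(peak["end"]),
                        float(peak["amplitude"]),
                        REGION_PROMOTER if abs(d) <= promoter else REGION_ENHANCER,
                        float(d),
                    )
                )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def strongest_enhancer_peak(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the enhancer peak with the highest amplitude.

    Ties break toward the smaller |distance_to_tss|, then the smaller start.
    Genes without an enhancer peak are simply absent.
    """
    enh = assignments[assignments["region_class"] == REGION_ENHANCER]
    if enh.empty:
        return enh.copy()
    ranked = enh.assign(_absd=enh["distance_to_tss"].abs()).sort_values(
        ["gene_id", "amplitude", "_absd", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    out = ranked.groupby("gene_id", sort=True).head(1).drop(columns="_absd")
    log.info("strongest enhancer peak selected for %d genes", len(out))
    return out.reset_index(drop=True)


def nearest_gene(
    peak_chrom: str,
    peak_start: int,
    peak_end: int,
    ann: GeneAnnotation,
    tss_mode: str = "strand",
) -> str | None:
    """Gene whose TSS is closest to the peak midpoint; ties break to the
    lexicographically smallest gene_id.  None when the chromosome has no
    annotated gene (logged)."""
    sub = ann.df[ann.df["chrom"] == peak_chrom]
    if sub.empty:
        log.warning("no annotated genes on %s; peak left unassigned", peak_chrom)
        return None
    tss = ann.tss(mode=tss_mode).loc[sub["gene_id"].to_numpy()]
    mid = (peak_start + peak_end) / 2.0
    dist = (tss - mid).abs()
    best = dist.min()
    candidates = sorted(dist.index[dist == best])
    return candidates[0]
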
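"""Containers and readers/writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout
the package; sources that use 1-based inclusive coordinates are converted
on read.  Coverage tracks are piecewise-constant signals; bedGraph is the
text representation used everywhere, with bigWig supported behind the same
interface when pyBigWig is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("grtime")

PEAK_COLUMNS = ["chrom", "start", "end", "name", "amplitude"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountsTable:
    """Gene x sample expression matrix with per-sample time/replicate metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id, one column per sample; values >= 0.
    sample_meta
        DataFrame indexed by sample name with columns ``time_hours`` (>= 0)
        and ``replicate`` (integer >= 1).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"sample(s) missing from metadata: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative count encountered")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        if self.sample_meta["time_hours"].isna().any():
            bad = self.sample_meta.index[self.sample_meta["time_hours"].isna()][0]
            raise ValueError(f"sample {bad!r} has no time annotation")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")

    @property
    def times(self) -> np.ndarray:
        """Sorted unique time points (hours)."""
        return np.sort(self.sample_meta["time_hours"].unique())

    def samples_at(self, time_hours: float) -> list[str]:
        m = self.sample_meta["time_hours"] == time_hours
        return list(self.sample_meta.index[m])

    def mean_by_time(self) -> pd.DataFrame:
        """Replicate-averaged gene x time matrix, columns sorted by time."""
        out = {}
        for t in self.times:
            out[t] = self.counts[self.samples_at(t)].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class GeneAnnotation:
    """Per-gene coordinates: chrom, start/end (0-based half-open), strand,
    transcript length.  The TSS is strand-aware by default (start for ``+``,
    end for ``-``)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"gene_id", "chrom", "start", "end", "strand", "transcript_length"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene with start >= end")
        if (self.df["transcript_length"] <= 0).any():
            raise ValueError("non-positive transcript_length")
        self.df = self.df.reset_index(drop=True)

    def tss(self, mode: str = "strand") -> pd.Series:
        """TSS position per gene.

        mode="strand": start for + genes, end for - genes.
        mode="naive-start": the lower coordinate regardless of strand.
        """
        if mode == "naive-start":
            pos = self.df["start"].astype(float)
        elif mode == "strand":
            pos = np.where(
                self.df["strand"] == "+", self.df["start"], self.df["end"]
            ).astype(float)
            pos = pd.Series(pos, index=self.df.index)
        else:
            raise ValueError(f"unknown tss mode {mode!r}")
        return pd.Series(np.asarray(pos, dtype=float), index=self.df["gene_id"].to_numpy())


@dataclass
class PeakSet:
    """Scored genomic intervals for one factor at one time point.

    ``df`` columns: chrom, start, end, name, amplitude; 0-based half-open,
    sorted by (chrom, start).
    """

    df: pd.DataFrame
    factor: str = ""
    time_hours: float = float("nan")
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.df.empty:
            self.df = pd.DataFrame(columns=PEAK_COLUMNS)
            return
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("peak with start >= end")
        if (self.df["amplitude"] < 0).any():
            raise ValueError("negative peak amplitude")
        self.df = (
            self.df.sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0


class CoverageTrack:
    """Piecewise-constant non-negative genome signal with interval queries.

    Stores per chromosome three parallel arrays (starts, ends, values) of
    non-overlapping segments sorted by start.  Bases not covered by any
    segment have value 0: they participate in means and never raise.
    """

    def __init__(self, factor: str = "", time_hours: float = float("nan")):
        self.factor = factor
        self.time_hours = time_hours
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self._warned: set[str] = set()

    def add_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="mergesort")
        starts, ends, values = starts[order], ends[order], values[order]
        if (values < 0).any():
            raise ValueError("negative coverage value")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
        # cumulative integral of the signal up to each segment end
        cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        self._chroms[chrom] = (starts, ends, values, cum)

    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def _get(self, chrom: str):
        seg = self._chroms.get(chrom)
        if seg is None and chrom not in self._warned:
            log.warning("coverage query on absent chromosome %r -> 0", chrom)
            self._warned.add(chrom)
        return seg

    def max(self, chrom: str, start: int, end: int) -> float:
        """Maximum signal over [start, end); 0 where uncovered."""
        seg = self._get(chrom)
        if seg is None:
            return 0.0
        starts, ends, values, _ = seg
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        return float(values[i0:i1].max(initial=0.0))

    def _cumulative(self, seg, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over (-inf, pos) for an array of positions."""
        starts, ends, values, cum = seg
        pos = np.asarray(pos, dtype=float)
        j = np.searchsorted(ends, pos, side="right")
        out = cum[j]
        inside = j < len(starts)
        if inside.any():
            part = np.clip(pos[inside] - starts[j[inside]], 0.0, None)
            out[inside] = out[inside] + values[j[inside]] * part
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty interval")
        seg = self._get(chrom)
        if seg is None:
            return 0.0
        lo, hi = self._cumulative(seg, np.array([start, end], dtype=float))
        return float((hi - lo) / (end - start))

    def binned_means(self, chrom: str, start: int, n_bins: int, width: int) -> np.ndarray:
        """Mean signal in ``n_bins`` consecutive bins of ``width`` bp from ``start``."""
        seg = self._get(chrom)
        if seg is None:
            return np.zeros(n_bins)
        edges = start + width * np.arange(n_bins + 1, dtype=float)
        c = self._cumulative(seg, edges)
        return np.diff(c) / width

    def argmax(self, chrom: str, start: int, end: int) -> int:
        """Leftmost base position attaining the maximum over [start, end)."""
        seg = self._get(chrom)
        if seg is None:
            return int(start)
        starts, ends, values, _ = seg
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return int(start)
        best = float(values[i0:i1].max(initial=0.0))
        if best <= 0.0:
            return int(start)
        # first uncovered base before the first segment counts as 0 < best
        for k in range(i0, i1):
            if values[k] == best:
                return int(max(starts[k], start))
        return int(start)  # pragma: no cover


# ---------------------------------------------------------------------------
# readers


def read_counts(path, meta_path) -> CountsTable:
    """Read a gene x sample count TSV plus a sample metadata TSV.

    The counts file has a header row; its first column is the gene id.  The
    metadata file maps sample -> (time_hours, replicate).
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    for col in counts.columns:
        bad = pd.to_numeric(counts[col], errors="coerce").isna() & counts[col].notna()
        if bad.any() or counts[col].isna().any():
            row = counts.index[bad | counts[col].isna()][0]
            raise ValueError(f"non-numeric count at gene {row!r}, sample {col!r}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample(s) missing from metadata: {missing}")
    return CountsTable(counts.astype(float), meta)


def write_counts(table: CountsTable, path, meta_path) -> None:
    table.counts.sort_index().to_csv(path, sep="\t", index_label="gene_id")
    table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_annotation(path, one_based: bool = False) -> GeneAnnotation:
    """Read a gene annotation TSV; ``one_based=True`` converts 1-based
    inclusive starts to the internal 0-based half-open convention."""
    df = pd.read_csv(path, sep="\t")
    if one_based:
        df["start"] = df["start"] - 1
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.df.sort_values(["chrom", "start"]).to_csv(path, sep="\t", index=False)


def read_narrowpeak(path, factor: str = "", time_hours: float = float("nan")) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) or BED5 file.

    The per-peak amplitude is the narrowPeak signalValue (column 7) when
    present, else the BED score (column 5).  The BED score is capped at 1000
    by the format, so signalValue is preferred as the actual measurement.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >= 5 columns, got {len(parts)}")
            amplitude = float(parts[6]) if len(parts) >= 7 else float(parts[4])
            rows.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3], amplitude)
            )
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(df, factor=factor, time_hours=time_hours)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Write a PeakSet as narrowPeak with the amplitude in signalValue."""
    with open(path, "w") as fh:
        for rec in peaks.df.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t0\t.\t"
                f"{rec.amplitude:g}\t-1\t-1\t-1\n"
            )


def _read_bedgraph(path, factor: str, time_hours: float) -> CoverageTrack:
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    track = CoverageTrack(factor=factor, time_hours=time_hours)
    for chrom, sub in df.groupby("chrom", sort=True):
        track.add_chrom(
            str(chrom),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(),
        )
    return track


def _read_bigwig(path, factor: str, time_hours: float) -> CoverageTrack:
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    try:
        track = CoverageTrack(factor=factor, time_hours=time_hours)
        for chrom in bw.chroms():
            ivals = bw.intervals(chrom)
            if not ivals:
                continue
            starts, ends, values = zip(*ivals)
            track.add_chrom(chrom, starts, ends, values)
        return track
    finally:
        bw.close()


def read_coverage(path, factor: str = "", time_hours: float = float("nan")) -> CoverageTrack:
    """Read a coverage track (bedGraph text, or bigWig when pyBigWig is
    installed), dispatching on the file suffix."""
    suffix = Path(path).suffix.lower()
    try:
        if suffix in {".bw", ".bigwig"}:
            return _read_bigwig(path, factor, time_hours)
        return _read_bedgraph(path, factor, time_hours)
    except (OSError, RuntimeError, ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot read coverage track {path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values, _ = track._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
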
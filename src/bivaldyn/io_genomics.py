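"""Core genomic types and plain-text readers/writers.

All coordinates are 0-based, half-open (BED convention).  Offsets relative
to a transcription start site (TSS) are expressed in *transcription
orientation*: negative offsets are upstream of the TSS on the coding
strand, so a promoter window of (-3000, -100) sits 5' of the gene on
either strand.

Peak files are a declared BED5+ dialect: tab-separated
``chrom  start  end  height  area`` with optional ``#``-prefixed header
lines.  ``height`` is the summit intensity of the enriched region and
``area`` the cumulative intensity under its coverage curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MARKS = ("H3K4me3", "H3K27me3")
TIMEPOINTS = ("t0", "t8", "t24", "reox8")


class ParseError(ValueError):
    """A malformed input file (carries the offending path and line)."""


# ---------------------------------------------------------------------------
# interval / peak / gene containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared basepairs (0 if on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap(other) > 0


@dataclass(frozen=True)
class Peak:
    """An enriched interval with summit height and cumulative area.

    The area accumulates at most ``height`` per covered basepair, so
    ``area <= height * length`` always, with equality only for a
    rectangular profile; a width-1 peak must carry its full height.
    """

    interval: GenomicInterval
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.height < 0 or self.area < 0:
            raise ValueError("peak height and area must be nonnegative")
        length = self.interval.length
        if self.area > self.height * length * (1 + 1e-9):
            raise ValueError(
                f"peak area {self.area} exceeds height*length "
                f"({self.height}*{length})"
            )
        if length == 1 and self.area < self.height * (1 - 1e-9):
            raise ValueError("width-1 peak must have area >= height")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def scaled(self, factor: float) -> "Peak":
        """Return a copy with height and area multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Peak(self.interval, self.height * factor, self.area * factor)


@dataclass
class PeakSet:
    """All peaks of one mark in one sample (time point).

    ``scale_factor`` records the cumulative multiplicative normalization
    already applied to heights and areas (1.0 for raw peak-caller output).
    """

    mark: str
    timepoint: str
    peaks: list[Peak]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.chrom, p.start, p.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def label(self) -> str:
        return f"{self.mark}:{self.timepoint}"

    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks], dtype=float)

    def apply_scale(self, factor: float) -> "PeakSet":
        """Return a new PeakSet with all intensities multiplied by ``factor``."""
        return PeakSet(
            mark=self.mark,
            timepoint=self.timepoint,
            peaks=[p.scaled(factor) for p in self.peaks],
            scale_factor=self.scale_factor * factor,
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene spanning its 5'-most TSS to the end of its last exon."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-'"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (a single base position)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def gene_length(self) -> int:
        return self.interval.length

    def tx_interval(self, start_offset: int, end_offset: int) -> GenomicInterval:
        """Map an offset window [start_offset, end_offset) in transcription
        orientation onto genomic coordinates (clamped at position 0).

        Offset 0 is the TSS base itself; negative offsets are upstream.
        """
        if start_offset >= end_offset:
            raise ValueError("need start_offset < end_offset")
        if self.strand == "+":
            s = self.tss + start_offset
            e = self.tss + end_offset
        else:
            s = self.tss - end_offset + 1
            e = self.tss - start_offset + 1
        return GenomicInterval(self.chrom, max(0, s), e, self.strand)

    def analysis_region(self, flank: int) -> GenomicInterval:
        """Gene body extended symmetrically by ``flank`` bp on both sides."""
        return gene_analysis_region(self, flank)


def gene_analysis_region(gene: GeneModel, flank: int) -> GenomicInterval:
    """The genic analysis region: gene body plus ``flank`` bp up- and
    downstream (strand-independent), clamped at chromosome position 0."""
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    iv = gene.interval
    return GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand)


# ---------------------------------------------------------------------------
# expression container
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples.

    Columns are labelled ``<timepoint>_<replicate>``.  ``detection_floor``
    and ``expressed_threshold`` are optional log2 thresholds attached once
    determined (the floor from never-expressed control genes, the
    expressed threshold from a linear-scale cutoff).
    """

    data: pd.DataFrame
    timepoints: tuple[str, ...]
    detection_floor: float | None = None
    expressed_threshold: float | None = None

    def __post_init__(self) -> None:
        self.timepoints = tuple(self.timepoints)
        seen: dict[str, int] = {}
        for col in self.data.columns:
            tp = str(col).rsplit("_", 1)[0]
            if tp not in self.timepoints:
                raise ValueError(
                    f"column {col!r} does not match any timepoint "
                    f"{self.timepoints}"
                )
            seen[tp] = seen.get(tp, 0) + 1
        for tp in self.timepoints:
            if seen.get(tp, 0) < 2:
                raise ValueError(
                    f"timepoint {tp!r} has fewer than 2 replicates"
                )
        if (
            self.detection_floor is not None
            and self.expressed_threshold is not None
            and self.detection_floor > self.expressed_threshold
        ):
            raise ValueError("detection_floor must not exceed expressed_threshold")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_for(self, timepoint: str) -> list[str]:
        return [
            c for c in self.data.columns if str(c).rsplit("_", 1)[0] == timepoint
        ]

    def timepoint_means(self) -> pd.DataFrame:
        """Per-gene mean over replicates, one column per time point."""
        out = {}
        for tp in self.timepoints:
            out[tp] = self.data[self.columns_for(tp)].mean(axis=1)
        return pd.DataFrame(out, index=self.data.index)


# ---------------------------------------------------------------------------
# pipeline parameters
# ---------------------------------------------------------------------------


@dataclass
class PipelineParams:
    """All numeric knobs of the pipeline with their default settings.

    Region offsets are in transcription orientation relative to the TSS.
    ``expressed_threshold_units`` is on the linear (non-log2) scale.
    """

    window_size_bp: int = 20_000
    high_peak_percentile: float = 90.0
    flank_bp: int = 5_000
    promoter_region: tuple[int, int] = (-3000, -100)
    tss_region: tuple[int, int] = (-100, 1000)
    broad_start_offset: int = 1000
    min_gene_length_bp: int = 4000
    profile_margin: float = 1.25
    expressed_threshold_units: float = 100.0
    highly_expressed_percentile: float = 95.0
    fc_log2_min: float = 2.0
    qvalue_max: float = 0.05
    window_test_alpha: float = 0.05
    cutoff_clean_fraction: float = 0.95
    tss_half_window_bp: int = 5000
    tss_bin_bp: int = 50

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0 or self.flank_bp < 0:
            raise ValueError("window/flank sizes must be positive")
        for pct in (self.high_peak_percentile, self.highly_expressed_percentile):
            if not 0 < pct < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        if self.profile_margin <= 1:
            raise ValueError("profile_margin must exceed 1")
        if not 0 <= self.cutoff_clean_fraction <= 1:
            raise ValueError("cutoff_clean_fraction must lie in [0, 1]")
        if self.min_gene_length_bp <= 0 or self.broad_start_offset <= 0:
            raise ValueError("gene-length parameters must be positive")
        if 2 * self.tss_half_window_bp % self.tss_bin_bp != 0:
            raise ValueError("tss bin width must divide the profile window")

    @property
    def expressed_threshold_log2(self) -> float:
        return math.log2(self.expressed_threshold_units)


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals per chromosome (strand
    discarded); returned sorted by (chrom, start)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or abut
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


class PeakIndex:
    """Per-chromosome sorted arrays for fast interval-overlap queries.

    ``min_height`` drops peaks with height <= min_height at build time
    (strictly-above semantics, matching the background-cutoff rule).
    """

    def __init__(self, peaks: Iterable[Peak], min_height: float | None = None):
        buckets: dict[str, list[Peak]] = {}
        n = 0
        for p in peaks:
            if min_height is not None and not p.height > min_height:
                continue
            buckets.setdefault(p.chrom, []).append(p)
            n += 1
        self.n_peaks = n
        self._chrom: dict[str, tuple[np.ndarray, ...]] = {}
        for chrom, plist in buckets.items():
            plist.sort(key=lambda p: (p.start, p.end))
            starts = np.array([p.start for p in plist], dtype=np.int64)
            ends = np.array([p.end for p in plist], dtype=np.int64)
            heights = np.array([p.height for p in plist], dtype=float)
            areas = np.array([p.area for p in plist], dtype=float)
            cummax_end = np.maximum.accumulate(ends)
            self._chrom[chrom] = (starts, ends, heights, areas, cummax_end)

    def query(
        self, chrom: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (starts, ends, heights, areas) of peaks overlapping
        [start, end) by at least one basepair."""
        empty = (np.empty(0, np.int64), np.empty(0, np.int64),
                 np.empty(0, float), np.empty(0, float))
        if chrom not in self._chrom or start >= end:
            return empty
        starts, ends, heights, areas, cummax_end = self._chrom[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi == 0:
            return empty
        lo = int(np.searchsorted(cummax_end[:hi], start, side="right"))
        mask = ends[lo:hi] > start
        sl = slice(lo, hi)
        return starts[sl][mask], ends[sl][mask], heights[sl][mask], areas[sl][mask]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, mark: str, timepoint: str) -> PeakSet:
    """Read a BED5+ peak file (chrom, start, end, height, area)."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path} line {lineno}: expected >= 5 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                height, area = float(fields[3]), float(fields[4])
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), height, area)
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return PeakSet(mark=mark, timepoint=timepoint, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\theight\tarea\n")
        for p in peakset:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.height:.10g}\t{p.area:.10g}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a 5-column TSV: gene_id, chrom, start, end, strand."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0] == "gene_id":  # tolerated bare header row
                continue
            if len(fields) < 5:
                raise ParseError(
                    f"{path} line {lineno}: expected 5 fields, got {len(fields)}"
                )
            gene_id, chrom = fields[0], fields[1]
            if gene_id in seen:
                raise ParseError(f"{path} line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            strand = fields[4]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path} line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                start, end = int(fields[2]), int(fields[3])
                genes.append(
                    GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}\n"
            )


def read_expression(
    path: str | Path, timepoints: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV with ``<timepoint>_<replicate>`` columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if timepoints is None:
        tps: list[str] = []
        for col in df.columns:
            tp = str(col).rsplit("_", 1)[0]
            if tp not in tps:
                tps.append(tp)
        timepoints = tps
    return ExpressionMatrix(data=df.astype(float), timepoints=tuple(timepoints))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and ``#`` comments skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_ids):
            fh.write(f"{gid}\n")
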
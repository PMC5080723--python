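"""Genic/intergenic peak partition, per-gene mark calls, and TSS-centered
average intensity profiles.

A gene's *analysis region* is its body (5'-most TSS to last exon) plus a
symmetric flank; a gene is *marked* when at least one peak strictly above
the background cutoff overlaps that region by >= 1 bp.  For H3K4me3 the
peak caller's own significance filter is assumed already applied, so the
default cutoff is 0 (every peak counts); the invariant-region cutoff from
normalization applies to H3K27me3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_genomics import (
    GeneModel,
    PeakIndex,
    PeakSet,
    merge_intervals,
)


@dataclass
class TSSProfile:
    """Mean peak intensity around the TSS, genes oriented 5'->3'.

    ``offsets`` are bin left edges in bp relative to the TSS (negative =
    upstream in transcription orientation).
    """

    offsets: np.ndarray
    mean_intensity: np.ndarray
    n_genes: int
    bin_size: int


def partition_peaks(
    peakset: PeakSet, genes: Sequence[GeneModel], flank: int = 5000
) -> tuple[list, list]:
    """Split peaks into genic (overlapping any gene's analysis region by
    >= 1 bp) and intergenic lists.  Apply the background cutoff to the
    peak set before calling if background peaks should be excluded."""
    regions = merge_intervals([g.analysis_region(flank) for g in genes])
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        rs = [r for r in regions if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
    genic, intergenic = [], []
    for p in peakset:
        hit = False
        if p.chrom in by_chrom:
            starts, ends = by_chrom[p.chrom]
            # merged regions are sorted and disjoint: the first region
            # ending after the peak start is the only overlap candidate
            i = int(np.searchsorted(ends, p.start, side="right"))
            hit = i < len(starts) and starts[i] < p.end
        (genic if hit else intergenic).append(p)
    return genic, intergenic


def partition_fractions(
    peakset: PeakSet, genes: Sequence[GeneModel], flank: int = 5000
) -> dict[str, float]:
    genic, intergenic = partition_peaks(peakset, genes, flank)
    total = len(genic) + len(intergenic)
    return {
        "n_genic": len(genic),
        "n_intergenic": len(intergenic),
        "genic_fraction": len(genic) / total if total else float("nan"),
        "intergenic_fraction": len(intergenic) / total if total else float("nan"),
    }


def call_gene_marks(
    genes: Sequence[GeneModel],
    peakset: PeakSet,
    cutoff: float = 0.0,
    flank: int = 5000,
) -> pd.DataFrame:
    """One mark call per gene: marked iff >= 1 peak with height strictly
    above ``cutoff`` overlaps the gene's analysis region.

    Returns a DataFrame indexed by gene id with columns ``mark``,
    ``timepoint``, ``marked``, ``n_overlapping_peaks``, ``max_height``.
    """
    index = PeakIndex(peakset.peaks, min_height=cutoff)
    rows = []
    for g in genes:
        region = g.analysis_region(flank)
        _, _, heights, _ = index.query(region.chrom, region.start, region.end)
        n = int(len(heights))
        rows.append(
            {
                "gene_id": g.gene_id,
                "mark": peakset.mark,
                "timepoint": peakset.timepoint,
                "marked": n >= 1,
                "n_overlapping_peaks": n,
                "max_height": float(heights.max()) if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def marked_ids(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["marked"]])


def tss_profile(
    peakset: PeakSet,
    genes: Sequence[GeneModel],
    half_window: int = 5000,
    bin_size: int = 50,
    cutoff: float = 0.0,
) -> TSSProfile:
    """Average peak height per position around the TSS across genes.

    Every gene is considered in the same 5'->3' orientation (minus-strand
    windows are mirrored).  Within one gene, overlapping peaks contribute
    the maximum height per position (heights are summit statistics, not
    additive); the per-position profile is then averaged over all genes
    and summarized in fixed-width bins.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if (2 * half_window) % bin_size != 0:
        raise ValueError("bin_size must divide the profile window evenly")
    index = PeakIndex(peakset.peaks, min_height=cutoff)
    width = 2 * half_window
    total = np.zeros(width)
    gene_arr = np.empty(width)
    for g in genes:
        gene_arr[:] = 0.0
        tss = g.tss
        if g.strand == "+":
            w0, w1 = tss - half_window, tss + half_window
        else:
            w0, w1 = tss - half_window + 1, tss + half_window + 1
        starts, ends, heights, _ = index.query(g.chrom, max(0, w0), w1)
        for s, e, h in zip(starts, ends, heights):
            lo = max(int(s), w0)
            hi = min(int(e), w1)
            if g.strand == "+":
                a, b = lo - w0, hi - w0
            else:  # mirror: genomic position p -> offset tss - p
                a, b = w1 - hi, w1 - lo
            np.maximum(gene_arr[a:b], h, out=gene_arr[a:b])
        total += gene_arr
    mean_per_bp = total / len(genes) if genes else total
    binned = mean_per_bp.reshape(-1, bin_size).mean(axis=1)
    offsets = np.arange(-half_window, half_window, bin_size)
    return TSSProfile(
        offsets=offsets,
        mean_intensity=binned,
        n_genes=len(genes),
        bin_size=bin_size,
    )
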
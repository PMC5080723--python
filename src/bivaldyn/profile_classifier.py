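"""Region-specific H3K27me3 profile classification.

Each H3K27me3-marked gene is divided into three strand-aware regions in
transcription orientation relative to the TSS: the promoter region
(-3000/-100 bp), the TSS region (-100/+1000 bp), and the broad region
(+1000 bp to the last exon).  The *size-scaled enrichment density* of a
region is the sum over above-cutoff peaks of height x overlapping bp,
divided by the region length.  A gene is

* ``Promoter`` / ``TSS`` class when that region's density is at least
  ``profile_margin`` (default 1.25, i.e., "25% more") times the density
  of *each* other region (boundary ties accepted),
* ``Broad`` when at least one above-cutoff peak overlaps the broad
  region and neither sharp class applies (blanketing enrichment),
* ``TooShort`` when the gene body is under 4 kb (too small for a
  reliable assignment), and
* ``Unclassified`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_genomics import GeneModel, PeakIndex, PeakSet, PipelineParams

CLASSES = ("Promoter", "TSS", "Broad", "Unclassified", "TooShort")


@dataclass
class ProfileCall:
    gene_id: str
    timepoint: str
    klass: str
    d_promoter: float
    d_tss: float
    d_broad: float


def region_density(
    gene: GeneModel,
    index: PeakIndex,
    bounds: tuple[int, int],
    cutoff: float = 0.0,
) -> float:
    """Size-scaled summarized enrichment of one tx-orientation region.

    ``bounds`` are offsets relative to the TSS; the density divides by
    the nominal region length regardless of clamping at position 0.
    Peaks at or below ``cutoff`` contribute nothing.
    """
    a, b = bounds
    length = b - a
    if length <= 0:
        raise ValueError("region bounds must have positive length")
    region = gene.tx_interval(a, b)
    starts, ends, heights, _ = index.query(region.chrom, region.start, region.end)
    if len(starts) == 0:
        return 0.0
    mask = heights > cutoff
    if not mask.any():
        return 0.0
    overlap = np.minimum(ends[mask], region.end) - np.maximum(starts[mask], region.start)
    return float(np.sum(heights[mask] * overlap) / length)


def classify_gene(
    gene: GeneModel,
    index: PeakIndex,
    params: PipelineParams | None = None,
    cutoff: float = 0.0,
    timepoint: str = "",
) -> ProfileCall:
    """Assign one H3K27me3-marked gene to a profile class."""
    params = params or PipelineParams()
    if gene.gene_length < params.min_gene_length_bp:
        return ProfileCall(gene.gene_id, timepoint, "TooShort", 0.0, 0.0, 0.0)

    d_prom = region_density(gene, index, params.promoter_region, cutoff)
    d_tss = region_density(gene, index, params.tss_region, cutoff)
    broad_bounds = (params.broad_start_offset, gene.gene_length)
    d_broad = region_density(gene, index, broad_bounds, cutoff)

    m = params.profile_margin
    if d_prom > 0 and d_prom >= m * d_tss and d_prom >= m * d_broad:
        klass = "Promoter"
    elif d_tss > 0 and d_tss >= m * d_prom and d_tss >= m * d_broad:
        klass = "TSS"
    else:
        region = gene.tx_interval(*broad_bounds)
        _, _, heights, _ = index.query(region.chrom, region.start, region.end)
        klass = "Broad" if np.any(heights > cutoff) else "Unclassified"
    return ProfileCall(gene.gene_id, timepoint, klass, d_prom, d_tss, d_broad)


def classify_genes(
    genes: Sequence[GeneModel],
    peakset: PeakSet,
    cutoff: float = 0.0,
    params: PipelineParams | None = None,
    marked_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify every (marked) gene against one H3K27me3 sample.

    When ``marked_ids`` is given, only those genes are classified (the
    class is defined for marked genes); otherwise all genes are scored.
    """
    params = params or PipelineParams()
    index = PeakIndex(peakset.peaks)
    keep = set(marked_ids) if marked_ids is not None else None
    rows = []
    for g in genes:
        if keep is not None and g.gene_id not in keep:
            continue
        call = classify_gene(g, index, params, cutoff, peakset.timepoint)
        rows.append(
            {
                "gene_id": call.gene_id,
                "timepoint": call.timepoint,
                "klass": call.klass,
                "d_promoter": call.d_promoter,
                "d_tss": call.d_tss,
                "d_broad": call.d_broad,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "timepoint", "klass", "d_promoter", "d_tss", "d_broad"],
    ).set_index("gene_id")
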
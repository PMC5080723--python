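"""Invariant-region normalization of broad-mark ChIP-seq samples.

Broad repressive marks such as H3K27me3 lack a stable global reference
between libraries, so between-sample scaling is anchored on *invariant
regions*: genomic windows whose high-intensity enrichment is present in
every sample.  The procedure is:

1. For each sample, flag "high" peaks (height above the sample's 90th
   percentile) and test each fixed-size genome window for enrichment of
   high-peak basepair coverage against the genome-wide expectation
   (one-sided binomial test).
2. Windows enriched in *all* samples are invariant; abutting invariant
   windows are merged into maximal regions.
3. Each sample's cumulative peak area (AUC) within the invariant
   regions is computed, apportioning peak area by overlap fraction,
   and scaled relative to the smallest AUC among the samples:
   ``factor_i = min_j(AUC_j) / AUC_i``.  The smallest-AUC sample anchors
   at 1.0 and all factors lie in (0, 1].
4. After scaling, a single background height cutoff for all samples is
   chosen from consistently highly expressed genes: the smallest value
   below which a required fraction of those genes shows no remaining
   H3K27me3 peak in their analysis region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_genomics import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakIndex,
    PeakSet,
    PipelineParams,
)


class NormalizationError(RuntimeError):
    """Raised when scale factors cannot be defined (e.g., no invariant
    region exists); the pipeline aborts rather than skip normalization."""


@dataclass
class WindowEnrichment:
    """Per-window high-peak coverage and enrichment p-values for one sample."""

    sample: str
    windows: list[GenomicInterval]
    coverage_frac: np.ndarray
    pvalues: np.ndarray
    high_threshold: float
    expected_frac: float


@dataclass
class InvariantRegionSet:
    """Merged windows enriched for high peaks in every sample."""

    regions: list[GenomicInterval]
    window_size: int
    windows: list[GenomicInterval]
    per_window_pvalues: dict[str, np.ndarray]

    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class NormalizationResult:
    invariant_regions: InvariantRegionSet
    scale_factors: dict[str, float]  # sample label -> factor in (0, 1]
    background_cutoff: float  # height threshold in post-scaling units
    achieved_clean_fraction: float
    highly_expressed_ids: list[str]


def infer_chrom_lengths(
    samples: Sequence[PeakSet], genes: Sequence[GeneModel] | None = None
) -> dict[str, int]:
    """Smallest per-chromosome span covering all peaks (and genes)."""
    lengths: dict[str, int] = {}
    for ps in samples:
        for p in ps:
            lengths[p.chrom] = max(lengths.get(p.chrom, 0), p.end)
    for g in genes or []:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.interval.end)
    return lengths


def tile_windows(
    chrom_lengths: Mapping[str, int], window_size: int
) -> list[GenomicInterval]:
    """Fixed-size windows tiling each chromosome from position 0; a
    trailing partial window is dropped to keep the binomial expectation
    uniform across windows."""
    windows: list[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        n_full = chrom_lengths[chrom] // window_size
        for i in range(n_full):
            windows.append(
                GenomicInterval(chrom, i * window_size, (i + 1) * window_size)
            )
    return windows


def coverage_pvalue(covered_bp: int, window_bp: int, expected_frac: float) -> float:
    """One-sided binomial tail P(X >= covered_bp) for X ~ Bin(window_bp,
    expected_frac): is this window's high-peak coverage above the
    genome-wide expectation?"""
    if covered_bp <= 0:
        return 1.0
    return float(stats.binom.sf(covered_bp - 1, window_bp, expected_frac))


def _merged_high_intervals(peakset: PeakSet, threshold: float) -> list[GenomicInterval]:
    from .io_genomics import merge_intervals

    high = [p.interval for p in peakset if p.height > threshold]
    return merge_intervals(high) if high else []


def window_high_peak_enrichment(
    peakset: PeakSet,
    windows: Sequence[GenomicInterval],
    percentile: float = 90.0,
) -> WindowEnrichment:
    """High-peak coverage fraction and binomial enrichment p-value per
    window for one sample.

    "High" peaks are those with height strictly above the sample's
    ``percentile`` height.  Coverage counts merged high-peak basepairs,
    so overlapping peaks are not double counted.
    """
    heights = peakset.heights()
    if len(heights) < 10:
        raise NormalizationError(
            f"sample {peakset.label} has {len(heights)} peaks; "
            "height percentile is meaningless below 10"
        )
    threshold = float(np.percentile(heights, percentile))
    merged = _merged_high_intervals(peakset, threshold)

    # windows are a fixed tiling from 0; locate them by (chrom, start//size)
    sizes = {w.length for w in windows}
    if len(sizes) != 1:
        raise ValueError("windows must share one size")
    wsize = sizes.pop()
    index_of = {(w.chrom, w.start // wsize): i for i, w in enumerate(windows)}
    coverage = np.zeros(len(windows), dtype=np.int64)
    for iv in merged:
        first = iv.start // wsize
        last = (iv.end - 1) // wsize
        for wi in range(first, last + 1):
            key = (iv.chrom, wi)
            if key not in index_of:
                continue
            lo = max(iv.start, wi * wsize)
            hi = min(iv.end, (wi + 1) * wsize)
            coverage[index_of[key]] += hi - lo

    total_bp = wsize * len(windows)
    expected = float(coverage.sum()) / total_bp if total_bp else 0.0
    pvals = np.array(
        [coverage_pvalue(int(c), wsize, expected) for c in coverage]
    )
    return WindowEnrichment(
        sample=peakset.label,
        windows=list(windows),
        coverage_frac=coverage / wsize,
        pvalues=pvals,
        high_threshold=threshold,
        expected_frac=expected,
    )


def find_invariant_regions(
    samples: Sequence[PeakSet],
    params: PipelineParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> InvariantRegionSet:
    """Windows enriched (p < alpha) in every sample, merged when abutting.

    Raises :class:`NormalizationError` if no window qualifies, since
    scale factors would be undefined without an anchor.
    """
    params = params or PipelineParams()
    if len(samples) < 2:
        raise NormalizationError("need >= 2 samples to define invariant regions")
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(samples)
    windows = tile_windows(chrom_lengths, params.window_size_bp)
    if not windows:
        raise NormalizationError("no complete window fits the genome")

    per_window: dict[str, np.ndarray] = {}
    invariant = np.ones(len(windows), dtype=bool)
    for ps in samples:
        enr = window_high_peak_enrichment(ps, windows, params.high_peak_percentile)
        per_window[ps.label] = enr.pvalues
        invariant &= enr.pvalues < params.window_test_alpha
    if not invariant.any():
        raise NormalizationError(
            "no invariant window found in all samples; normalization is "
            "undefined — check that samples share stable high-intensity "
            "domains or relax window_test_alpha"
        )
    from .io_genomics import merge_intervals

    regions = merge_intervals([windows[i] for i in np.flatnonzero(invariant)])
    return InvariantRegionSet(
        regions=regions,
        window_size=params.window_size_bp,
        windows=windows,
        per_window_pvalues=per_window,
    )


def compute_scale_factors(
    samples: Sequence[PeakSet],
    invariant_regions: InvariantRegionSet | Sequence[GenomicInterval],
) -> dict[str, float]:
    """Per-sample factors equalizing cumulative peak area (AUC) within
    the invariant regions: ``factor_i = min_j(AUC_j) / AUC_i``.

    Peaks straddling a region boundary contribute their area apportioned
    by overlap fraction.
    """
    regions = (
        invariant_regions.regions
        if isinstance(invariant_regions, InvariantRegionSet)
        else list(invariant_regions)
    )
    if not regions:
        raise NormalizationError("invariant region set is empty")
    aucs: dict[str, float] = {}
    for ps in samples:
        index = PeakIndex(ps.peaks)
        auc = 0.0
        for region in regions:
            starts, ends, _, areas = index.query(region.chrom, region.start, region.end)
            if len(starts) == 0:
                continue
            overlap = np.minimum(ends, region.end) - np.maximum(starts, region.start)
            frac = overlap / (ends - starts)
            auc += float(np.sum(areas * frac))
        if auc <= 0:
            raise NormalizationError(
                f"sample {ps.label} has zero peak area in the invariant regions"
            )
        aucs[ps.label] = auc
    smallest = min(aucs.values())
    return {label: smallest / auc for label, auc in aucs.items()}


def apply_scale_factors(
    samples: Sequence[PeakSet], factors: Mapping[str, float]
) -> list[PeakSet]:
    return [ps.apply_scale(factors[ps.label]) for ps in samples]


def set_background_cutoff(
    k27_samples_scaled: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    expression: ExpressionMatrix,
    params: PipelineParams | None = None,
) -> tuple[float, float, list[str]]:
    """Single post-scaling height cutoff below which peaks are background.

    Anchored on genes whose expression exceeds the per-sample
    ``highly_expressed_percentile`` in *all* samples: repressive-mark
    peaks at consistently highly expressed genes are biologically
    implausible, so the cutoff is the smallest height at which at least
    ``cutoff_clean_fraction`` of those genes retain no above-cutoff
    H3K27me3 peak in their analysis region.

    Returns ``(cutoff, achieved_clean_fraction, highly_expressed_ids)``.
    """
    params = params or PipelineParams()
    values = expression.data
    thresholds = values.quantile(params.highly_expressed_percentile / 100.0, axis=0)
    above_all = (values > thresholds).all(axis=1)
    high_ids = [gid for gid in values.index[above_all] if gid in {g.gene_id for g in genes}]
    if not high_ids:
        raise NormalizationError(
            "no consistently highly expressed gene found; cannot anchor the "
            "background cutoff"
        )
    gene_by_id = {g.gene_id: g for g in genes}
    indexes = [PeakIndex(ps.peaks) for ps in k27_samples_scaled]
    max_heights = np.zeros(len(high_ids))
    for i, gid in enumerate(high_ids):
        region = gene_by_id[gid].analysis_region(params.flank_bp)
        m = 0.0
        for index in indexes:
            _, _, heights, _ = index.query(region.chrom, region.start, region.end)
            if len(heights):
                m = max(m, float(heights.max()))
        max_heights[i] = m

    f = params.cutoff_clean_fraction
    if f <= 0:
        return 0.0, float(np.mean(max_heights <= 0.0)), high_ids
    k = int(np.ceil(f * len(max_heights)))
    cutoff = float(np.sort(max_heights)[k - 1])
    achieved = float(np.mean(max_heights <= cutoff))
    return cutoff, achieved, high_ids


def normalize_k27(
    k27_samples: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    expression: ExpressionMatrix,
    params: PipelineParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[NormalizationResult, list[PeakSet]]:
    """Full normalization stage: invariant regions, scale factors,
    scaled samples, and the validated background cutoff."""
    params = params or PipelineParams()
    invariant = find_invariant_regions(k27_samples, params, chrom_lengths)
    factors = compute_scale_factors(k27_samples, invariant)
    scaled = apply_scale_factors(k27_samples, factors)
    cutoff, achieved, high_ids = set_background_cutoff(
        scaled, genes, expression, params
    )
    result = NormalizationResult(
        invariant_regions=invariant,
        scale_factors=factors,
        background_cutoff=cutoff,
        achieved_clean_fraction=achieved,
        highly_expressed_ids=high_ids,
    )
    return result, scaled
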
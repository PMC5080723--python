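"""Region densities against a per-basepair brute-force oracle, and the
Promoter/TSS/Broad decision rule."""

from __future__ import annotations

import numpy as np
import pytest

from bivaldyn.io_genomics import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakIndex,
    PeakSet,
    PipelineParams,
)
from bivaldyn.profile_classifier import (
    CLASSES,
    classify_gene,
    classify_genes,
    region_density,
)

PARAMS = PipelineParams()


def _peak(chrom, start, end, height):
    return Peak(GenomicInterval(chrom, start, end), height, height * (end - start) * 0.7)


def brute_force_density(gene, peaks, bounds, cutoff=0.0):
    """Independent oracle: count covered basepairs of the region by
    position-by-position enumeration, then accumulate height x coverage."""
    region = gene.tx_interval(*bounds)
    length = bounds[1] - bounds[0]
    total = 0.0
    for p in peaks:
        if p.chrom != region.chrom or not p.height > cutoff:
            continue
        covered = sum(
            1 for pos in range(region.start, region.end) if p.start <= pos < p.end
        )
        total += p.height * covered
    return total / length


def test_density_hand_arithmetic():
    gene = GeneModel("g", GenomicInterval("chr1", 50_000, 60_000, "+"))
    # peak covering 900 bp of the 2900-bp promoter window
    peaks = [_peak("chr1", 47_000, 47_900, 10.0)]
    d = region_density(gene, PeakIndex(peaks), PARAMS.promoter_region)
    assert d == pytest.approx(10.0 * 900 / 2900)
    assert region_density(gene, PeakIndex([]), PARAMS.promoter_region) == 0.0


def test_density_equals_brute_force_on_random_genes():
    rng = np.random.default_rng(123)
    for _ in range(200):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(10_000, 50_000))
        length = int(rng.integers(4000, 12_000))
        gene = GeneModel("g", GenomicInterval("chr1", start, start + length, strand))
        peaks = []
        for _ in range(int(rng.integers(0, 8))):
            s = int(rng.integers(max(0, start - 6000), start + length + 2000))
            w = int(rng.integers(50, 2500))
            peaks.append(_peak("chr1", s, s + w, float(rng.uniform(0.5, 20.0))))
        index = PeakIndex(peaks)
        for bounds in (PARAMS.promoter_region, PARAMS.tss_region, (1000, length)):
            got = region_density(gene, index, bounds, cutoff=2.0)
            want = brute_force_density(gene, peaks, bounds, cutoff=2.0)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_density_strand_mirror_twins():
    plus = GeneModel("p", GenomicInterval("chr1", 50_000, 58_000, "+"))
    minus = GeneModel("m", GenomicInterval("chr1", 50_000, 58_000, "-"))
    peaks_plus = [_peak("chr1", 47_500, 48_500, 6.0)]  # offsets (-2500,-1500)
    peaks_minus = [_peak("chr1", 59_500, 60_500, 6.0)]  # same offsets for minus
    d_plus = region_density(plus, PeakIndex(peaks_plus), PARAMS.promoter_region)
    d_minus = region_density(minus, PeakIndex(peaks_minus), PARAMS.promoter_region)
    assert d_plus == d_minus > 0


GENE = GeneModel("g", GenomicInterval("chr1", 50_000, 60_000, "+"))


def _call(peaks, gene=GENE, cutoff=0.0, params=PARAMS):
    return classify_gene(gene, PeakIndex(peaks), params, cutoff)


def test_sole_tss_peak_classifies_tss():
    call = _call([_peak("chr1", 50_000, 50_900, 8.0)])
    assert call.klass == "TSS"
    assert call.d_promoter == call.d_broad == 0.0


def test_short_gene_excluded():
    short = GeneModel("s", GenomicInterval("chr1", 50_000, 53_500, "+"))
    assert _call([_peak("chr1", 50_000, 50_900, 8.0)], gene=short).klass == "TooShort"


def test_equal_densities_are_unclassified():
    # equal promoter and TSS densities, empty broad region: neither sharp
    # class reaches the 1.25x margin and no broad peak exists
    peaks = [
        _peak("chr1", 47_000, 49_900, 2.0),  # full promoter coverage
        _peak("chr1", 49_900, 51_000, 2.0),  # full TSS-region coverage
    ]
    assert _call(peaks).klass == "Unclassified"


def test_margin_boundary_tie_accepted():
    # promoter density exactly 1.25x the TSS density wins (>= rule)
    peaks = [
        _peak("chr1", 47_000, 49_900, 2.5),  # d_prom = 2.5
        _peak("chr1", 49_900, 51_000, 2.0),  # d_tss = 2.0
    ]
    assert _call(peaks).klass == "Promoter"


def test_broad_needs_above_cutoff_peak_in_gene_body():
    body = [_peak("chr1", 51_000, 59_000, 6.0)]
    assert _call(body).klass == "Broad"
    assert _call(body, cutoff=6.0).klass == "Unclassified"
    # dominated sharp regions with extra body signal still go Broad
    mixed = [
        _peak("chr1", 47_000, 49_900, 4.0),
        _peak("chr1", 49_900, 51_000, 4.0),
        _peak("chr1", 52_000, 58_000, 4.0),
    ]
    assert _call(mixed).klass == "Broad"


def test_scaling_invariance_of_classes(sim, normalized):
    _, genes, _, gt, _ = sim
    _, scaled = normalized
    cut = gt.cutoff_in_scaled_units()
    mids = sorted(gt.k27_marked("t0"))[:40]
    a = classify_genes(genes, scaled["t0"], cut, PARAMS, mids)
    tripled = scaled["t0"].apply_scale(3.0)
    b = classify_genes(genes, tripled, cut * 3.0, PARAMS, mids)
    assert (a["klass"] == b["klass"]).all()


def test_every_marked_gene_gets_exactly_one_class(sim, normalized):
    _, genes, _, gt, _ = sim
    _, scaled = normalized
    cut = gt.cutoff_in_scaled_units()
    mids = gt.k27_marked("t8")
    calls = classify_genes(genes, scaled["t8"], cut, PARAMS, mids)
    assert len(calls) == len(mids)
    assert set(calls["klass"]) <= set(CLASSES)


def test_designed_classes_recovered(sim, normalized):
    _, genes, _, gt, _ = sim
    _, scaled = normalized
    cut = gt.cutoff_in_scaled_units()
    for tp in ("t0", "t8"):
        mids = gt.k27_marked(tp)
        calls = classify_genes(genes, scaled[tp], cut, PARAMS, mids)
        truth = gt.k27_profile[tp]
        classifiable = calls[calls["klass"] != "TooShort"]
        agree = (classifiable["klass"] == truth.loc[classifiable.index]).mean()
        assert agree >= 0.95
        # the short-gene route matches the ground-truth bookkeeping
        assert set(calls.index[calls["klass"] == "TooShort"]) == (
            gt.short_genes & mids
        )
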
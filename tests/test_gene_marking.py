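"""Genic/intergenic partition, mark-call rules, and TSS profiles."""

from __future__ import annotations

import numpy as np
import pytest

from bivaldyn.gene_marking import (
    call_gene_marks,
    marked_ids,
    partition_fractions,
    partition_peaks,
    tss_profile,
)
from bivaldyn.io_genomics import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    TIMEPOINTS,
)


def _peak(chrom, start, end, height=10.0):
    return Peak(GenomicInterval(chrom, start, end), height, height * (end - start) * 0.8)


GENE = GeneModel("g1", GenomicInterval("chr1", 20_000, 40_000, "+"))
# analysis region with 5-kb flank: [15000, 45000)


def test_partition_respects_half_open_boundaries():
    genes = [GENE]
    abutting = _peak("chr1", 45_000, 45_500)  # starts exactly at region end
    one_bp = _peak("chr1", 44_999, 45_400)
    genic, intergenic = partition_peaks(
        PeakSet("H3K4me3", "t0", [abutting, one_bp]), genes, 5000
    )
    assert [p.start for p in genic] == [44_999]
    assert [p.start for p in intergenic] == [45_000]


def test_partition_fraction_matches_brute_force():
    genes = [
        GENE,
        GeneModel("g2", GenomicInterval("chr2", 100_000, 110_000, "-")),
    ]
    inside = [
        _peak("chr1", 16_000, 16_500),
        _peak("chr1", 39_000, 41_000),
        _peak("chr2", 95_500, 96_000),
        _peak("chr2", 108_000, 109_000),
        _peak("chr2", 114_000, 114_500),
        _peak("chr1", 14_500, 15_100),
    ]
    outside = [
        _peak("chr1", 1_000, 2_000),
        _peak("chr1", 50_000, 51_000),
        _peak("chr2", 10_000, 11_000),
        _peak("chr3", 16_000, 16_500),
    ]
    ps = PeakSet("H3K27me3", "t0", inside + outside)
    # brute force: per-peak any-bp overlap against every gene region
    regions = [g.analysis_region(5000) for g in genes]
    expected_genic = sum(
        1 for p in ps if any(r.overlap(p.interval) > 0 for r in regions)
    )
    frac = partition_fractions(ps, genes, 5000)
    assert frac["n_genic"] == expected_genic == 6
    assert frac["genic_fraction"] == pytest.approx(0.6)
    assert frac["genic_fraction"] + frac["intergenic_fraction"] == pytest.approx(1.0)


def test_mark_call_requires_strictly_above_cutoff():
    at_cutoff = PeakSet("H3K27me3", "t0", [_peak("chr1", 25_000, 26_000, height=5.0)])
    calls = call_gene_marks([GENE], at_cutoff, cutoff=5.0)
    assert not calls.loc["g1", "marked"]
    calls = call_gene_marks([GENE], at_cutoff, cutoff=4.999)
    assert calls.loc["g1", "marked"]
    assert calls.loc["g1", "max_height"] == 5.0


def test_mark_call_empty_peakset():
    calls = call_gene_marks([GENE], PeakSet("H3K4me3", "t0", []))
    assert not calls.loc["g1", "marked"]
    assert calls.loc["g1", "n_overlapping_peaks"] == 0


def test_lowering_cutoff_never_unmarks(sim, normalized):
    _, genes, _, _, _ = sim
    _, scaled = normalized
    high = marked_ids(call_gene_marks(genes, scaled["t0"], cutoff=6.0))
    low = marked_ids(call_gene_marks(genes, scaled["t0"], cutoff=2.0))
    assert high <= low


def test_marked_sets_recover_ground_truth(sim, normalized):
    _, genes, peaksets, gt, _ = sim
    _, scaled = normalized
    cut = gt.cutoff_in_scaled_units()
    for tp in TIMEPOINTS:
        k27 = marked_ids(call_gene_marks(genes, scaled[tp], cut))
        assert k27 == gt.k27_marked(tp)
        k4 = marked_ids(call_gene_marks(genes, peaksets[("H3K4me3", tp)], 0.0))
        assert k4 == gt.k4_marked


# --- TSS profiles -----------------------------------------------------------


def test_profile_projects_peak_heights():
    gene = GeneModel("g1", GenomicInterval("chr1", 50_000, 60_000, "+"))
    ps = PeakSet("H3K4me3", "t0", [_peak("chr1", 49_900, 50_100, height=5.0)])
    prof = tss_profile(ps, [gene], half_window=1000, bin_size=50)
    covered = (prof.offsets >= -100) & (prof.offsets < 100)
    assert np.allclose(prof.mean_intensity[covered], 5.0)
    assert np.allclose(prof.mean_intensity[~covered], 0.0)


def test_profile_strand_symmetry():
    plus = GeneModel("p", GenomicInterval("chr1", 50_000, 60_000, "+"))
    minus = GeneModel("m", GenomicInterval("chr1", 50_000, 60_000, "-"))
    # peak spanning offsets [+100, +400) of each gene in tx orientation
    ps_plus = PeakSet("H3K4me3", "t0", [_peak("chr1", 50_100, 50_400, 7.0)])
    ps_minus = PeakSet("H3K4me3", "t0", [_peak("chr1", 59_600, 59_900, 7.0)])
    prof_plus = tss_profile(ps_plus, [plus], 1000, 50)
    prof_minus = tss_profile(ps_minus, [minus], 1000, 50)
    np.testing.assert_allclose(prof_plus.mean_intensity, prof_minus.mean_intensity)


def test_profile_symmetric_landscape_is_symmetric():
    gene = GeneModel("g", GenomicInterval("chr1", 50_000, 60_000, "+"))
    ps = PeakSet(
        "H3K4me3",
        "t0",
        [_peak("chr1", 49_200, 49_900, 4.0), _peak("chr1", 50_100, 50_800, 4.0)],
    )
    prof = tss_profile(ps, [gene], 1000, 50)
    np.testing.assert_allclose(prof.mean_intensity, prof.mean_intensity[::-1])


def test_profile_overlapping_peaks_take_max_not_sum():
    gene = GeneModel("g", GenomicInterval("chr1", 50_000, 60_000, "+"))
    ps = PeakSet(
        "H3K27me3",
        "t0",
        [_peak("chr1", 49_900, 50_100, 3.0), _peak("chr1", 49_950, 50_050, 9.0)],
    )
    prof = tss_profile(ps, [gene], 200, 50)
    assert prof.mean_intensity.max() == pytest.approx(9.0)


def test_k4_landscape_shows_tss_depletion(sim):
    """The simulated H3K4me3 geometry reproduces the characteristic dip
    directly over the TSS between two flanking peaks."""
    _, genes, peaksets, gt, _ = sim
    k4_genes = [g for g in genes if g.gene_id in gt.k4_marked]
    prof = tss_profile(peaksets[("H3K4me3", "t0")], k4_genes, 2000, 50)
    center = prof.mean_intensity[np.abs(prof.offsets) < 50].mean()
    flank = prof.mean_intensity[(np.abs(prof.offsets) >= 200) & (np.abs(prof.offsets) < 800)].mean()
    assert center < 0.2 * flank


def test_profile_validates_window():
    with pytest.raises(ValueError):
        tss_profile(PeakSet("H3K4me3", "t0", []), [], half_window=0)
    with pytest.raises(ValueError):
        tss_profile(PeakSet("H3K4me3", "t0", []), [], half_window=1000, bin_size=300)
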
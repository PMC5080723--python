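"""Invariant-region detection, scale-factor arithmetic, and the
expression-anchored background cutoff."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bivaldyn.io_genomics import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    PipelineParams,
    TIMEPOINTS,
)
from bivaldyn.normalization import (
    NormalizationError,
    compute_scale_factors,
    coverage_pvalue,
    find_invariant_regions,
    set_background_cutoff,
    tile_windows,
    window_high_peak_enrichment,
)


def _rect(chrom, start, end, height):
    return Peak(GenomicInterval(chrom, start, end), height, height * (end - start) * 0.8)


def _sample(tp, peaks):
    return PeakSet("H3K27me3", tp, peaks)


def _landscape(tp, domains, chrom_len=200_000, low_height=1.0, high_height=100.0):
    """Many low scattered peaks (>90% of the sample, so the 90th height
    percentile sits at the low level) plus fully tiled high domains."""
    peaks = [
        _rect("chr1", s, s + 200, low_height) for s in range(1000, chrom_len - 1000, 300)
    ]
    for d0, d1 in domains:
        for s in range(d0, d1, 1000):
            peaks.append(_rect("chr1", s, min(s + 1000, d1), high_height))
    return _sample(tp, peaks)


CHROM_LEN = {"chr1": 200_000}
PARAMS = PipelineParams()


def test_tile_windows_drops_partial_tail():
    wins = tile_windows({"chr1": 50_000}, 20_000)
    assert [(w.start, w.end) for w in wins] == [(0, 20_000), (20_000, 40_000)]


def test_coverage_pvalue_closed_form():
    assert coverage_pvalue(0, 20_000, 0.01) == 1.0
    # full coverage against a tiny expectation is essentially impossible
    assert coverage_pvalue(20_000, 20_000, 0.01) < 1e-100
    # coverage exactly at the genome-wide expectation is unremarkable
    from scipy.stats import binom

    expected = coverage_pvalue(200, 20_000, 0.01)
    assert expected == pytest.approx(float(binom.sf(199, 20_000, 0.01)))
    assert expected >= 0.5


def test_enrichment_requires_enough_peaks():
    wins = tile_windows(CHROM_LEN, 20_000)
    tiny = _sample("t0", [_rect("chr1", 0, 100, 1.0)])
    with pytest.raises(NormalizationError, match="percentile"):
        window_high_peak_enrichment(tiny, wins)


def test_enrichment_flags_high_domain_windows_only():
    wins = tile_windows(CHROM_LEN, 20_000)
    ps = _landscape("t0", domains=[(40_000, 100_000)])
    enr = window_high_peak_enrichment(ps, wins, 90.0)
    enriched = enr.pvalues < 0.05
    # windows 2..4 carry the domain; all others hold only sub-percentile peaks
    assert list(np.flatnonzero(enriched)) == [2, 3, 4]
    assert enr.coverage_frac[2] == pytest.approx(1.0)
    assert enr.coverage_frac[0] == 0.0


def test_invariant_regions_require_all_samples_and_merge():
    samples = [_landscape(tp, [(40_000, 100_000)]) for tp in TIMEPOINTS]
    inv = find_invariant_regions(samples, PARAMS, CHROM_LEN)
    assert len(inv.regions) == 1
    region = inv.regions[0]
    assert region.start == 40_000 and region.end == 100_000
    assert region.length >= 3 * PARAMS.window_size_bp

    # same domain missing from one sample -> nothing is invariant
    samples[-1] = _landscape("reox8", domains=[])
    with pytest.raises(NormalizationError, match="no invariant window"):
        find_invariant_regions(samples, PARAMS, CHROM_LEN)


def test_invariant_windows_separated_by_gap_stay_separate():
    domains = [(20_000, 40_000), (60_000, 80_000)]  # windows 1 and 3
    samples = [_landscape(tp, domains) for tp in ("t0", "t8")]
    inv = find_invariant_regions(samples, PARAMS, CHROM_LEN)
    assert [(r.start, r.end) for r in inv.regions] == [
        (20_000, 40_000),
        (60_000, 80_000),
    ]


def test_invariant_detection_unaffected_by_uniform_rescaling():
    samples = [_landscape(tp, [(40_000, 100_000)]) for tp in TIMEPOINTS]
    inv_a = find_invariant_regions(samples, PARAMS, CHROM_LEN)
    rescaled = [samples[0].apply_scale(3.0)] + samples[1:]
    inv_b = find_invariant_regions(rescaled, PARAMS, CHROM_LEN)
    assert inv_a.regions == inv_b.regions


def test_scale_factors_follow_auc_arithmetic():
    region = [GenomicInterval("chr1", 0, 20_000)]
    samples = [
        _sample(tp, [Peak(GenomicInterval("chr1", 100, 1100), 10.0, area)])
        for tp, area in zip(("t0", "t8", "t24"), (100.0, 200.0, 400.0))
    ]
    factors = compute_scale_factors(samples, region)
    assert factors == {
        "H3K27me3:t0": 1.0,
        "H3K27me3:t8": 0.5,
        "H3K27me3:t24": 0.25,
    }


def test_scale_factors_identity_and_idempotence(sim, normalized):
    result, scaled = normalized
    # identical samples -> all factors 1
    ps = scaled["t0"]
    same = [PeakSet("H3K27me3", tp, list(ps.peaks)) for tp in ("t0", "t8")]
    factors = compute_scale_factors(same, result.invariant_regions)
    assert all(f == pytest.approx(1.0) for f in factors.values())
    # re-running on already-scaled samples is a no-op
    refactors = compute_scale_factors(list(scaled.values()), result.invariant_regions)
    assert all(f == pytest.approx(1.0, rel=1e-6) for f in refactors.values())


def test_scale_factor_apportions_straddling_peak_area():
    region = [GenomicInterval("chr1", 0, 10_000)]
    inside = _sample("t0", [Peak(GenomicInterval("chr1", 100, 1100), 10.0, 100.0)])
    # peak half inside the region: only half its area counts
    straddle = _sample(
        "t8", [Peak(GenomicInterval("chr1", 9000, 11_000), 10.0, 400.0)]
    )
    factors = compute_scale_factors([inside, straddle], region)
    assert factors["H3K27me3:t0"] == pytest.approx(1.0)
    assert factors["H3K27me3:t8"] == pytest.approx(0.5)


def test_scale_factor_zero_auc_errors():
    region = [GenomicInterval("chr2", 0, 10_000)]
    samples = [
        _sample("t0", [_rect("chr1", 0, 100, 1.0)]),
        _sample("t8", [_rect("chr1", 0, 100, 1.0)]),
    ]
    with pytest.raises(NormalizationError, match="zero peak area"):
        compute_scale_factors(samples, region)


def test_depth_factor_recovery_on_simulation(sim, normalized):
    cfg, _, _, gt, _ = sim
    result, _ = normalized
    d_min = min(gt.depth_factors.values())
    for tp, d in gt.depth_factors.items():
        got = result.scale_factors[f"H3K27me3:{tp}"]
        assert got == pytest.approx(d_min / d, rel=0.01)


# --- background cutoff ------------------------------------------------------


def test_cutoff_recovered_within_designed_bracket(sim, normalized):
    _, _, _, gt, _ = sim
    result, _ = normalized
    d_min = min(gt.depth_factors.values())
    assert 0.0 < result.background_cutoff < gt.min_signal_height * d_min
    assert result.background_cutoff <= gt.max_noise_height * d_min * (1 + 1e-9)
    assert result.achieved_clean_fraction >= 0.95


def test_cutoff_monotone_in_clean_fraction(sim, normalized):
    _, genes, _, _, expr = sim
    _, scaled = normalized
    samples = list(scaled.values())
    cuts = []
    for f in (0.0, 0.5, 0.9, 1.0):
        params = PipelineParams(cutoff_clean_fraction=f)
        c, _, _ = set_background_cutoff(samples, genes, expr, params)
        cuts.append(c)
    assert cuts[0] == 0.0
    assert cuts == sorted(cuts)


def test_cutoff_errors_without_consistent_high_expressers():
    genes = [GeneModel("g1", GenomicInterval("chr1", 1000, 6000, "+"))]
    df = pd.DataFrame(
        {f"{tp}_{r}": [5.0] for tp in ("t0", "t8") for r in (1, 2)}, index=["g1"]
    )
    expr = ExpressionMatrix(df, timepoints=("t0", "t8"))
    sample = _sample("t0", [_rect("chr1", 1000, 2000, 5.0)])
    with pytest.raises(NormalizationError, match="highly expressed"):
        set_background_cutoff([sample], genes, expr, PARAMS)
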
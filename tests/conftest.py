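"""Shared fixtures: one moderately sized simulated study reused across
module tests (session-scoped; everything is seeded and deterministic)."""

from __future__ import annotations

import pytest

from bivaldyn import SimulationConfig, simulate_all
from bivaldyn.io_genomics import TIMEPOINTS, PipelineParams
from bivaldyn.normalization import normalize_k27


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture(scope="session")
def sim():
    """Default-condition simulation at reduced gene count.

    Returns (config, genes, peaksets, ground_truth, expression).
    """
    cfg = SimulationConfig(
        n_genes=600, n_chroms=6, chrom_length_bp=6_000_000, seed=11
    )
    genes, peaksets, gt, expr = simulate_all(cfg)
    return cfg, genes, peaksets, gt, expr


@pytest.fixture(scope="session")
def normalized(sim, params):
    """Normalization of the shared simulation's H3K27me3 samples.

    Returns (result, scaled_by_timepoint).
    """
    _, genes, peaksets, _, expr = sim
    k27 = [peaksets[("H3K27me3", tp)] for tp in TIMEPOINTS]
    result, scaled = normalize_k27(k27, genes, expr, params)
    return result, {ps.timepoint: ps for ps in scaled}
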
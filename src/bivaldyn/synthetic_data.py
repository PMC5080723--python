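"""Seeded generator of peak landscapes, gene models and expression with
known ground truth.

The generator emulates the study design the pipeline targets: two histone
marks (H3K4me3, H3K27me3) profiled at four time points (normoxia t0,
hypoxia t8/t24, reoxygenation reox8) in one cell population, plus a
replicated log2 expression matrix.  Designed features:

* H3K4me3 peaks flank the TSS of "K4-marked" genes with a depletion gap
  directly over the TSS (nucleosome-free region).
* H3K27me3-marked genes carry one of three enrichment geometries —
  a distinct peak upstream of the TSS (Promoter profile), a peak over
  the TSS (TSS profile), or tiled "blanketing" coverage of the gene body
  (Broad profile) — with a configurable designed dominance margin of the
  assigned region over a weaker competitor region.
* Hypoxia induces TSS-directed H3K27me3 gain at a fraction of
  K4-premarked genes (t8/t24); a fraction of those gains is retained at
  reoxygenation, the rest reverts.
* Shared high-intensity H3K27me3 domains ("invariant regions") are
  present with identical geometry in every H3K27me3 sample before each
  sample's multiplicative depth distortion is applied.
* Background noise peaks sit strictly below a designed intensity cutoff
  (``hard_mode`` lets the noise distribution overlap the signal range).
* Expression medians depend on the gene's mark state per time point;
  a pool of never-expressed "null" genes provides the empirical
  detection floor.

Every assignment is recorded in :class:`GroundTruth` so downstream
inferences (scale factors, profile classes, mark states, transitions)
can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_genomics import (
    TIMEPOINTS,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    write_expression,
    write_gene_models,
    write_peaks,
)

STATES = ("none", "K4only", "K27only", "bivalent")


def _default_depth_factors() -> dict[str, float]:
    # Per-sample sequencing-depth distortions for the H3K27me3 samples;
    # realistic library-size spread around 1.
    return {"t0": 1.0, "t8": 0.8, "t24": 1.3, "reox8": 0.9}


def _default_state_medians() -> dict[str, float]:
    # log2 medians by mark state: active K4-only genes high, repressed
    # K27-only genes at the noise floor, bivalent genes intermediate.
    return {"none": 5.0, "K4only": 9.0, "K27only": 3.5, "bivalent": 7.5}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Proportions (fraction of genes K4-marked, the Promoter/TSS/Broad
    split among K27-marked genes, genic peak fractions) follow the
    marked-gene census of the profiled cell line at normoxia; the
    hypoxic K27 gain and reoxygenation retention fractions reproduce
    the roughly threefold bivalency increase and its partial
    persistence.
    """

    n_genes: int = 2000
    n_chroms: int = 8
    chrom_length_bp: int = 10_000_000
    seed: int = 0
    depth_factors: Mapping[str, float] = field(default_factory=_default_depth_factors)
    frac_k4_marked: float = 0.46
    frac_k27_profiles: tuple[float, float, float] = (0.02, 0.02, 0.05)
    hypoxia_k27_gain_frac: float = 0.15
    retention_frac: float = 0.55
    n_invariant_domains: int = 10
    invariant_domain_bp: int = 60_000
    class_margin: float = 2.0
    signal_height_range: tuple[float, float] = (10.0, 30.0)
    invariant_height_range: tuple[float, float] = (60.0, 90.0)
    noise_height_range: tuple[float, float] = (0.5, 4.0)
    designed_cutoff: float = 5.0
    n_noise_peaks: int = 3000
    k4_intergenic_frac: float = 0.16
    k27_genic_frac_t0: float = 0.41
    hard_mode: bool = False
    n_replicates: int = 3
    expr_state_medians: Mapping[str, float] = field(default_factory=_default_state_medians)
    expr_sd: float = 0.35
    expr_gene_sd: float = 1.5
    n_null_genes: int = 60
    null_median: float = 3.5
    null_sd: float = 0.08
    bivalent_dampening_log2: float = 0.75
    gene_length_log_mean: float = math.log(8000.0)
    gene_length_log_sd: float = 0.6
    min_gene_length_bp: int = 1500
    max_gene_length_bp: int = 60_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_chroms < 1 or self.chrom_length_bp < 200_000:
            raise ValueError("genome too small")
        fracs = [
            self.frac_k4_marked,
            self.hypoxia_k27_gain_frac,
            self.retention_frac,
            self.k4_intergenic_frac,
            self.k27_genic_frac_t0,
            *self.frac_k27_profiles,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("proportions must lie in [0, 1]")
        if sum(self.frac_k27_profiles) > 1:
            raise ValueError("K27 profile proportions must sum to <= 1")
        if any(d <= 0 for d in self.depth_factors.values()):
            raise ValueError("depth factors must be positive")
        if self.class_margin <= 1:
            raise ValueError("class_margin must exceed 1")
        if not self.hard_mode and (
            self.noise_height_range[1] >= self.designed_cutoff
            or self.signal_height_range[0] <= self.designed_cutoff
        ):
            raise ValueError(
                "designed cutoff must separate noise and signal heights"
            )

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))


@dataclass
class GroundTruth:
    """Ledger of every designed assignment and parameter."""

    gene_ids: list[str]
    k4_marked: set[str]
    k27_profile: pd.DataFrame  # genes x timepoints; values in {None, class}
    gained: set[str]
    retained: set[str]
    reassigned: dict[str, str]  # gene id -> originally assigned class
    short_genes: set[str]  # genes below the classifier's 4-kb minimum
    depth_factors: dict[str, float]
    designed_cutoff: float
    max_noise_height: float
    min_signal_height: float
    invariant_domains: list[GenomicInterval]
    null_gene_ids: set[str] = field(default_factory=set)

    def k27_marked(self, timepoint: str) -> set[str]:
        col = self.k27_profile[timepoint]
        return set(col.index[col.notna()])

    def state(self, gene_id: str, timepoint: str) -> str:
        k4 = gene_id in self.k4_marked
        k27 = pd.notna(self.k27_profile.at[gene_id, timepoint])
        if k4 and k27:
            return "bivalent"
        if k4:
            return "K4only"
        if k27:
            return "K27only"
        return "none"

    def states(self, timepoint: str) -> pd.Series:
        k4 = self.k27_profile.index.isin(self.k4_marked)
        k27 = self.k27_profile[timepoint].notna().to_numpy()
        out = np.where(
            k4 & k27, "bivalent", np.where(k4, "K4only", np.where(k27, "K27only", "none"))
        )
        return pd.Series(out, index=self.k27_profile.index, name=timepoint)

    def states_table(self) -> pd.DataFrame:
        return pd.DataFrame({tp: self.states(tp) for tp in self.k27_profile.columns})

    def cutoff_in_scaled_units(self) -> float:
        """The designed background cutoff after depth distortion and
        min-anchored rescaling (all samples land at base x min depth)."""
        return self.designed_cutoff * min(self.depth_factors.values())


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes of lognormal length on the genome.

    Genes occupy the first 80% of each chromosome with >= 12 kb gaps so
    that +-5 kb analysis regions never overlap between neighbours; the
    remaining 20% is reserved for intergenic signal and the shared
    high-intensity domains.  Lengths below 4 kb occur naturally and
    exercise the classifier's short-gene exclusion.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    lengths = np.clip(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, n),
        config.min_gene_length_bp,
        config.max_gene_length_bp,
    ).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)
    gaps = rng.integers(12_000, 20_000, size=n)

    chroms = list(config.chrom_names)
    cursor = {c: 10_000 for c in chroms}
    limit = int(0.80 * config.chrom_length_bp)
    genes: list[GeneModel] = []
    width = len(str(n))
    for i in range(n):
        placed = False
        for j in range(len(chroms)):
            chrom = chroms[(i + j) % len(chroms)]
            start = cursor[chrom]
            end = start + int(lengths[i])
            if end <= limit:
                genes.append(
                    GeneModel(
                        f"g{i:0{width}d}",
                        GenomicInterval(chrom, start, end, str(strands[i])),
                    )
                )
                cursor[chrom] = end + int(gaps[i])
                placed = True
                break
        if not placed:
            raise ValueError(
                "genome too small to place all genes; increase n_chroms or "
                "chrom_length_bp"
            )
    return genes


# ---------------------------------------------------------------------------
# peak landscapes
# ---------------------------------------------------------------------------


def _mk_peak(
    interval: GenomicInterval, height: float, rng: np.random.Generator
) -> Peak:
    area = height * interval.length * rng.uniform(0.6, 0.9)
    # peaks are unstranded even when derived from a gene's tx window
    iv = GenomicInterval(interval.chrom, interval.start, interval.end)
    return Peak(iv, height, area)


def _k27_gene_peaks(
    gene: GeneModel,
    klass: str,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[Peak]:
    """Peaks realizing one K27 profile class at one gene.

    Promoter/TSS classes get a dominant peak in the assigned region plus
    a weaker competitor peak whose size-scaled density is exactly
    ``class_margin``-fold lower, so classification at any margin below
    ``class_margin`` is recoverable by design.
    """
    lo, hi = config.signal_height_range
    m = config.class_margin
    peaks: list[Peak] = []
    if klass == "Promoter":
        h = rng.uniform(lo, hi)
        peaks.append(_mk_peak(gene.tx_interval(-2600, -400), h, rng))
        d_main = h * 2200 / 2900  # density over the 2900-bp promoter region
        h2 = d_main * 1100 / (500 * m)  # 500-bp peak in the 1100-bp TSS region
        peaks.append(_mk_peak(gene.tx_interval(0, 500), h2, rng))
    elif klass == "TSS":
        h = rng.uniform(lo, hi)
        peaks.append(_mk_peak(gene.tx_interval(-100, 1000), h, rng))
        d_main = h  # full coverage of the 1100-bp TSS region
        h2 = d_main * 2900 / (1000 * m)  # 1000-bp peak in the promoter region
        peaks.append(_mk_peak(gene.tx_interval(-2000, -1000), h2, rng))
    elif klass == "Broad":
        pos = 1000
        glen = gene.gene_length
        while pos < glen:
            w = int(rng.integers(800, 1601))
            w = min(w, glen - pos)
            if w < 100:
                break
            h = rng.uniform(lo, hi)
            peaks.append(_mk_peak(gene.tx_interval(pos, pos + w), h, rng))
            pos += w + int(rng.integers(50, 201))
    else:  # pragma: no cover - guarded by assignment logic
        raise ValueError(f"unknown K27 class {klass!r}")
    return peaks


def simulate_peaksets(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> tuple[dict[tuple[str, str], PeakSet], GroundTruth]:
    """Generate per-(mark, timepoint) peak sets plus the ground truth."""
    rng = np.random.default_rng([config.seed, 1])
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]

    # --- state assignments -------------------------------------------------
    k4_mask = rng.random(n) < config.frac_k4_marked
    u = rng.random(n)
    p_prom, p_tss, p_broad = config.frac_k27_profiles
    base_profile: list[str | None] = []
    reassigned: dict[str, str] = {}
    for i, g in enumerate(genes):
        if u[i] < p_prom:
            klass: str | None = "Promoter"
        elif u[i] < p_prom + p_tss:
            klass = "TSS"
        elif u[i] < p_prom + p_tss + p_broad:
            klass = "Broad"
        else:
            klass = None
        if klass == "Broad" and g.gene_length < 2500:
            # gene body too short to host blanketing coverage
            reassigned[g.gene_id] = "Broad"
            klass = "TSS"
        base_profile.append(klass)

    eligible = k4_mask & np.array([p is None for p in base_profile])
    gained_mask = eligible & (rng.random(n) < config.hypoxia_k27_gain_frac)
    retained_mask = gained_mask & (rng.random(n) < config.retention_frac)

    profile = pd.DataFrame(
        index=pd.Index(gene_ids, name="gene_id"),
        columns=list(TIMEPOINTS),
        dtype=object,
    )
    for i, gid in enumerate(gene_ids):
        base = base_profile[i]
        profile.at[gid, "t0"] = base
        profile.at[gid, "t8"] = base if base is not None else ("TSS" if gained_mask[i] else None)
        profile.at[gid, "t24"] = profile.at[gid, "t8"]
        profile.at[gid, "reox8"] = base if base is not None else ("TSS" if retained_mask[i] else None)

    # --- shared invariant domains (identical geometry in all K27 samples) --
    chroms = list(config.chrom_names)
    L = config.chrom_length_bp
    zone_start = int(0.86 * L)
    domains: list[GenomicInterval] = []
    domain_peaks: list[tuple[GenomicInterval, float]] = []
    ih_lo, ih_hi = config.invariant_height_range
    for d in range(config.n_invariant_domains):
        chrom = chroms[d % len(chroms)]
        offset = (d // len(chroms)) * (config.invariant_domain_bp + 50_000)
        s = zone_start + offset
        e = s + config.invariant_domain_bp
        if e > int(0.99 * L):
            raise ValueError("invariant domains do not fit the reserved zone")
        domains.append(GenomicInterval(chrom, s, e))
        pos = s
        while pos < e:
            w = min(500, e - pos)
            domain_peaks.append(
                (GenomicInterval(chrom, pos, pos + w), float(rng.uniform(ih_lo, ih_hi)))
            )
            pos += w

    min_signal = math.inf
    max_noise = 0.0

    def track_signal(peaks: list[Peak]) -> list[Peak]:
        nonlocal min_signal
        for p in peaks:
            min_signal = min(min_signal, p.height)
        return peaks

    peaksets: dict[tuple[str, str], PeakSet] = {}

    # --- H3K4me3 samples ---------------------------------------------------
    # K4 peak files stand in for sharp-mark peak-caller output already
    # filtered for significance, hence no sub-cutoff noise peaks here.
    for tp in TIMEPOINTS:
        peaks: list[Peak] = []
        for i, g in enumerate(genes):
            if not k4_mask[i]:
                continue
            h1, h2 = rng.uniform(15.0, 40.0, 2)
            peaks.append(_mk_peak(g.tx_interval(-900, -60), float(h1), rng))
            peaks.append(_mk_peak(g.tx_interval(60, 900), float(h2), rng))
        n_genic = len(peaks)
        f = config.k4_intergenic_frac
        n_inter = int(round(n_genic * f / (1 - f))) if f < 1 else 0
        for _ in range(n_inter):
            chrom = chroms[int(rng.integers(len(chroms)))]
            w = int(rng.integers(500, 1500))
            s = int(rng.integers(int(0.805 * L), int(0.845 * L) - w))
            peaks.append(
                _mk_peak(GenomicInterval(chrom, s, s + w), float(rng.uniform(15.0, 40.0)), rng)
            )
        peaksets[("H3K4me3", tp)] = PeakSet("H3K4me3", tp, peaks)

    # --- H3K27me3 samples --------------------------------------------------
    n_inter_extra_t0: int | None = None
    for tp in TIMEPOINTS:
        peaks = []
        n_genic = 0
        for i, g in enumerate(genes):
            klass = profile.at[g.gene_id, tp]
            if klass is None or (isinstance(klass, float) and pd.isna(klass)):
                continue
            gp = track_signal(_k27_gene_peaks(g, klass, rng, config))
            n_genic += len(gp)
            peaks.extend(gp)
        # intergenic signal: hold the t0 genic/intergenic partition near
        # the designed fraction, counting the shared domains as intergenic
        if n_inter_extra_t0 is None:
            f = config.k27_genic_frac_t0
            target_inter = int(round(n_genic * (1 - f) / f)) if f > 0 else 0
            n_inter_extra_t0 = max(0, target_inter - len(domain_peaks))
        for _ in range(n_inter_extra_t0):
            chrom = chroms[int(rng.integers(len(chroms)))]
            w = int(rng.integers(500, 2000))
            s = int(rng.integers(int(0.805 * L), int(0.845 * L) - w))
            lo, hi = config.signal_height_range
            peaks.extend(
                track_signal([_mk_peak(GenomicInterval(chrom, s, s + w), float(rng.uniform(lo, hi)), rng)])
            )
        # shared domains, identical across samples before depth distortion
        for iv, h in domain_peaks:
            area = h * iv.length * 0.75
            peaks.append(Peak(iv, h, area))
            min_signal = min(min_signal, h)
        # background noise
        nh_lo, nh_hi = config.noise_height_range
        if config.hard_mode:
            nh_hi = 2 * nh_hi
        for _ in range(config.n_noise_peaks):
            chrom = chroms[int(rng.integers(len(chroms)))]
            w = int(rng.integers(100, 400))
            s = int(rng.integers(0, int(0.99 * L) - w))
            h = float(rng.uniform(nh_lo, nh_hi))
            max_noise = max(max_noise, h)
            peaks.append(_mk_peak(GenomicInterval(chrom, s, s + w), h, rng))
        # per-sample multiplicative depth distortion
        factor = float(config.depth_factors.get(tp, 1.0))
        if factor != 1.0:
            peaks = [p.scaled(factor) for p in peaks]
        peaksets[("H3K27me3", tp)] = PeakSet("H3K27me3", tp, peaks)

    gt = GroundTruth(
        gene_ids=gene_ids,
        k4_marked={gene_ids[i] for i in range(n) if k4_mask[i]},
        k27_profile=profile,
        gained={gene_ids[i] for i in range(n) if gained_mask[i]},
        retained={gene_ids[i] for i in range(n) if retained_mask[i]},
        reassigned=reassigned,
        short_genes={g.gene_id for g in genes if g.gene_length < 4000},
        depth_factors={tp: float(config.depth_factors.get(tp, 1.0)) for tp in TIMEPOINTS},
        designed_cutoff=config.designed_cutoff,
        max_noise_height=max_noise,
        min_signal_height=min_signal if min_signal < math.inf else 0.0,
        invariant_domains=domains,
    )
    return peaksets, gt


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[GeneModel], ground_truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Replicated log2 expression whose medians track the mark state.

    Each gene carries a persistent baseline offset (biological
    between-gene variation) plus per-replicate Gaussian noise, so
    consistently highly expressed genes exist across all samples.  Null
    genes (never expressed) are appended as detection-floor donors and
    recorded in the ground truth.
    """
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    offsets = rng.normal(0.0, config.expr_gene_sd, n)
    # repressive-mark-carrying genes never reach the extreme top of the
    # expression distribution: cap their baseline offset so the
    # consistently-top-percentile population stays free of genuine
    # H3K27me3 signal (the premise of the background-cutoff validation)
    k27_any = ground_truth.k27_profile.notna().any(axis=1)
    for i, gid in enumerate(gene_ids):
        if k27_any[gid]:
            offsets[i] = min(offsets[i], 1.0)
    cols: dict[str, np.ndarray] = {}
    medians = dict(config.expr_state_medians)
    for tp in TIMEPOINTS:
        med = np.array(
            [medians[ground_truth.state(gid, tp)] for gid in gene_ids]
        )
        for rep in range(1, config.n_replicates + 1):
            cols[f"{tp}_{rep}"] = med + offsets + rng.normal(0.0, config.expr_sd, n)
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    width = len(str(max(config.n_null_genes, 1)))
    null_ids = [f"null_{i:0{width}d}" for i in range(config.n_null_genes)]
    if null_ids:
        null_vals = rng.normal(
            config.null_median, config.null_sd, (len(null_ids), df.shape[1])
        )
        df = pd.concat(
            [df, pd.DataFrame(null_vals, index=pd.Index(null_ids, name="gene_id"), columns=df.columns)]
        )
    ground_truth.null_gene_ids = set(null_ids)
    return ExpressionMatrix(data=df, timepoints=TIMEPOINTS)


def simulate_repeated_hypoxia_expression(
    genes: Sequence[GeneModel], ground_truth: GroundTruth, config: SimulationConfig
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Expression under repeated hypoxia/reoxygenation cycling.

    Conditions are baseline (t0) and 6 / 18 cycles of oxygen
    deprivation-reoxygenation.  Genes that gained and retained bivalent
    marking are progressively dampened (``bivalent_dampening_log2`` per
    condition step); a size-matched set of stably K4-only genes returns
    to its baseline level.  Both groups start from comparably low
    baseline expression, mirroring how such gene sets are selected.
    """
    rng = np.random.default_rng([config.seed, 3])
    gene_ids = [g.gene_id for g in genes]
    biv_group = sorted(ground_truth.gained & ground_truth.retained)
    k4_stable = sorted(
        gid
        for gid in ground_truth.k4_marked
        if gid not in ground_truth.gained
        and ground_truth.k27_profile.at[gid, "t0"] is None
    )
    size = min(len(biv_group), len(k4_stable))
    if size == 0:
        raise ValueError("no bivalent-gained or K4-stable genes in ground truth")
    k4_group = sorted(rng.choice(k4_stable, size=size, replace=False))

    conditions = ("t0", "cyc6", "cyc18")
    base = {gid: 5.0 for gid in gene_ids}
    for gid in biv_group + list(k4_group):
        base[gid] = 5.5  # low-expressed at baseline, above detection floor
    damp = config.bivalent_dampening_log2
    shift = {gid: 0.0 for gid in gene_ids}

    cols = {}
    offsets = dict(zip(gene_ids, rng.normal(0.0, 0.3, len(gene_ids))))
    for step, cond in enumerate(conditions):
        for gid in biv_group:
            shift[gid] = -damp * step
        med = np.array([base[g] + offsets[g] + shift[g] for g in gene_ids])
        for rep in range(1, config.n_replicates + 1):
            cols[f"{cond}_{rep}"] = med + rng.normal(0.0, config.expr_sd, len(gene_ids))
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    matrix = ExpressionMatrix(data=df, timepoints=conditions)
    groups = {"bivalent_gained": set(biv_group), "k4_only": set(k4_group)}
    return matrix, groups


def simulate_null_expression(
    n_genes: int,
    seed: int,
    n_replicates: int = 3,
    timepoints: Sequence[str] = ("t0", "t8", "t24"),
    median: float = 7.0,
    sd: float = 0.5,
) -> ExpressionMatrix:
    """Pure-noise expression: every gene shares one mean at all time
    points (for type-I error calibration of the differential tests)."""
    rng = np.random.default_rng([seed, 4])
    width = len(str(n_genes))
    ids = [f"n{i:0{width}d}" for i in range(n_genes)]
    cols = {
        f"{tp}_{rep}": median + rng.normal(0.0, sd, n_genes)
        for tp in timepoints
        for rep in range(1, n_replicates + 1)
    }
    return ExpressionMatrix(
        data=pd.DataFrame(cols, index=pd.Index(ids, name="gene_id")),
        timepoints=tuple(timepoints),
    )


# ---------------------------------------------------------------------------
# convenience / fixtures
# ---------------------------------------------------------------------------


def simulate_all(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[tuple[str, str], PeakSet], GroundTruth, ExpressionMatrix]:
    """Genome, peak landscapes, ground truth and expression in one call."""
    genes = simulate_genome(config)
    peaksets, gt = simulate_peaksets(genes, config)
    expr = simulate_expression(genes, gt, config)
    return genes, peaksets, gt, expr


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    """JSON-serializable dump of the ground truth ledger."""
    return {
        "gene_ids": gt.gene_ids,
        "k4_marked": sorted(gt.k4_marked),
        "k27_profile": {
            tp: {
                gid: gt.k27_profile.at[gid, tp]
                for gid in gt.gene_ids
                if pd.notna(gt.k27_profile.at[gid, tp])
            }
            for tp in gt.k27_profile.columns
        },
        "gained": sorted(gt.gained),
        "retained": sorted(gt.retained),
        "reassigned": dict(sorted(gt.reassigned.items())),
        "short_genes": sorted(gt.short_genes),
        "depth_factors": gt.depth_factors,
        "designed_cutoff": gt.designed_cutoff,
        "max_noise_height": gt.max_noise_height,
        "min_signal_height": gt.min_signal_height,
        "invariant_domains": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in gt.invariant_domains
        ],
        "null_gene_ids": sorted(gt.null_gene_ids),
    }


def write_fixtures(
    outdir: str | Path,
    genes: Sequence[GeneModel],
    peaksets: Mapping[tuple[str, str], PeakSet],
    ground_truth: GroundTruth,
    expression: ExpressionMatrix,
) -> dict[str, str]:
    """Write the full fixture set (peak BEDs, gene TSV, expression TSV,
    ground-truth JSON) and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_gene_models(genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    for (mark, tp), ps in sorted(peaksets.items()):
        p = outdir / f"peaks_{mark}_{tp}.bed"
        write_peaks(ps, p)
        paths[f"peaks:{mark}:{tp}"] = str(p)
    write_expression(expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth_to_dict(ground_truth), fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
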
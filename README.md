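# bivaldyn

Bivalent chromatin dynamics from peak-level ChIP-seq across
hypoxia/reoxygenation time courses.

## The problem

Solid tumors expose cells to cycles of oxygen deprivation and
reoxygenation.  Because histone lysine demethylases (KDMs) are
oxygen-dependent dioxygenases, hypoxia inhibits demethylation and the
activating H3K4me3 and repressive H3K27me3 trimethyl marks accumulate.
When H3K27me3 is gained at genes already carrying H3K4me3, the gene
becomes *bivalently* marked — a chromatin state associated with poised
developmental genes in embryonic stem cells.  Quantifying this process
from ChIP-seq requires a pipeline that (a) makes broad H3K27me3
libraries quantitatively comparable between samples, (b) calls per-gene
mark status, (c) distinguishes promoter-, TSS- and gene-body-directed
H3K27me3 geometries, (d) tracks mark-state transitions across time
points, and (e) relates mark states to gene expression.

`bivaldyn` implements this pipeline for peak-level inputs (a BED-like
table of enriched intervals with summit height and cumulative area per
mark and time point), together with a seeded synthetic-data generator
that produces full landscapes with known ground truth, so every stage
can be validated exactly.  It is written for computational biologists
analysing chromatin time courses, and for anyone who wants a tested,
reusable reference implementation of invariant-region normalization and
bivalency bookkeeping.

## The method

**Invariant-region normalization.**  For each sample, peaks with height
above the sample's 90th height percentile are "high".  Each 20-kb
genome window is tested for enrichment of high-peak basepair coverage
against the genome-wide expectation with a one-sided binomial test
(coverage `k` out of `n = 20 000` bp at background fraction `p̂`).
Windows enriched (`p < 0.05`) in **all** samples are *invariant*;
abutting invariant windows are merged.  With `AUC_i` the cumulative
peak area of sample `i` inside the invariant regions,

```
factor_i = min_j(AUC_j) / AUC_i            (factors in (0, 1])
```

equalizes invariant-region AUC across samples.  A single background
height cutoff `c` is then chosen from consistently highly expressed
genes (above the per-sample 95th expression percentile in every
sample): the smallest `c` such that ≥ 95 % of those genes retain no
H3K27me3 peak above `c` in their analysis region.

**Gene marking.**  A gene spans its 5′-most TSS to last-exon end plus
5 kb on both sides; it is *marked* when ≥ 1 above-cutoff peak overlaps
that region by ≥ 1 bp.

**H3K27me3 profile classes.**  Relative to the strand-aware TSS, the
promoter region is (−3000, −100), the TSS region (−100, +1000), and
the broad region (+1000, last exon).  With region density
`d = Σ height × overlap_bp / region_length` over above-cutoff peaks, a
gene (≥ 4 kb) is **Promoter** or **TSS** class when that density is
≥ 1.25× each other region's density, **Broad** when an above-cutoff
peak lies in the gene body and neither sharp class applies, otherwise
unclassified.

**Bivalency dynamics.**  Per time point each gene is `none`, `K4only`,
`K27only` or `bivalent` (both marks).  Transitions between time points
form a 4×4 count matrix; bivalency gains decompose into gain of
H3K4me3, of H3K27me3, or of both, and four-time-point trajectories are
labelled retained/lost relative to the reoxygenation endpoint.

**Expression integration.**  The detection floor is the maximum log2
expression of never-expressed control genes; a gene is *expressed*
when a per-time-point mean exceeds 100 linear units (log2 ≈ 6.64).
Differential expression uses two one-way ANOVA models (hypoxia arm
t0/t8/t24; reoxygenation arm t24/+8h/t0) with Benjamini–Hochberg FDR,
calling a gene significant when expressed, |Δlog2| ≥ 2 between two
time points of the model, and q ≤ 0.05.  Gene-set medians are compared
with the two-sided Mann–Whitney rank-sum test.

## Worked example

```python
from bivaldyn import SimulationConfig, simulate_all, PipelineParams
from bivaldyn.normalization import normalize_k27
from bivaldyn.gene_marking import call_gene_marks
from bivaldyn.bivalency_dynamics import mark_states, transitions
from bivaldyn.io_genomics import TIMEPOINTS

cfg = SimulationConfig(n_genes=600, n_chroms=6, chrom_length_bp=6_000_000, seed=11)
genes, peaksets, truth, expr = simulate_all(cfg)

params = PipelineParams()
k27_raw = [peaksets[("H3K27me3", tp)] for tp in TIMEPOINTS]
norm, k27_scaled = normalize_k27(k27_raw, genes, expr, params)
print("scale factors:", {k: round(v, 3) for k, v in norm.scale_factors.items()})
print("background cutoff:", round(norm.background_cutoff, 2),
      "| clean fraction:", round(norm.achieved_clean_fraction, 3))

scaled = {ps.timepoint: ps for ps in k27_scaled}
states = {}
for tp in TIMEPOINTS:
    k4 = call_gene_marks(genes, peaksets[("H3K4me3", tp)], cutoff=0.0)
    k27 = call_gene_marks(genes, scaled[tp], cutoff=norm.background_cutoff)
    states[tp] = mark_states(k4, k27)
    print(tp, "bivalent genes:", int((states[tp] == "bivalent").sum()))

tab = transitions(states["t0"], states["t8"], "t0", "t8")
print("bivalency gains t0->t8:", tab.summaries)
```

Output:

```
scale factors: {'H3K27me3:t0': 0.8, 'H3K27me3:t8': 1.0, 'H3K27me3:t24': 0.615, 'H3K27me3:reox8': 0.889}
background cutoff: 3.19 | clean fraction: 1.0
t0 bivalent genes: 26
t8 bivalent genes: 57
t24 bivalent genes: 57
reox8 bivalent genes: 46
bivalency gains t0->t8: {'bivalency_by_gain_of_K4': 0, 'bivalency_by_gain_of_K27': 33, 'bivalency_by_gain_of_both': 0, 'preexisting_bivalent': 24}
```

The generator distorted the four H3K27me3 libraries by depth factors
{1.0, 0.8, 1.3, 0.9}; the recovered scale factors are their inverses
anchored at the smallest-AUC sample (t8).  The cutoff 3.19 sits below
the designed signal range, so marked-gene recovery is exact: bivalency
rises from 26 genes at normoxia to 57 under hypoxia — entirely through
gain of H3K27me3 at H3K4me3-premarked genes — and 46 remain bivalent
after reoxygenation.

## Command line

Every stage is also a subcommand of the `bivaldyn` executable
(`simulate`, `normalize`, `mark`, `classify`, `bivalency`,
`expression`, `run-all`).  A full run from one YAML config:

```sh
bivaldyn run-all --config config.yaml
```

writes per-stage outputs plus a `manifest.json` capturing the config
snapshot, seed and output checksums; identical configs reproduce
identical bytes.

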
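# Methods

This note documents the models and procedures implemented in
`bivaldyn`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices at
the edges.

## Coordinate and orientation conventions

All intervals are 0-based, half-open (BED convention).  Offsets
relative to a TSS are in *transcription orientation*: offset 0 is the
TSS base, negative is upstream on the coding strand.  For a minus-strand
gene with TSS at genomic position `t`, the offset window `[a, b)` maps
to genomic `[t − b + 1, t − a + 1)`.  The genic analysis region (gene
body ± flank) extends symmetrically on both sides regardless of strand,
because peak files carry no strand and regulatory flanks are taken on
both ends of the gene; the flank default is 5 000 bp.

## Invariant-region normalization

Broad repressive marks lack an internal spike-in, so between-sample
comparability is anchored on genomic regions whose high-intensity
enrichment is stable across all samples.

*High peaks.*  Per sample, peaks strictly above the sample's 90th
height percentile.  Using a per-sample percentile makes the selection
invariant under uniform rescaling of a library, which is what a depth
distortion does.

*Window test.*  The genome is tiled with fixed windows (default
20 kb) from position 0; a trailing partial window per chromosome is
dropped so every window has the same size and the binomial expectation
is uniform.  For each window, merged high-peak coverage `k` (bp) is
tested one-sided against `Bin(window_size, p̂)` where `p̂` is the
fraction of all windowed basepairs covered by merged high peaks.  The
enrichment screen over windowed high-peak coverage replaces a
tiling-array sliding-window statistic with the natural peak-coverage
analogue; treating basepairs as independent trials is anti-conservative,
which is acceptable for a screen whose final criterion is intersection
across all samples.  Per-window α defaults to 0.05 with no
multiple-testing correction — the all-samples intersection is the
filter; a BH option can be layered on by lowering α.

*Scale factors.*  `factor_i = min_j(AUC_j) / AUC_i` with `AUC_i` the
summed peak area inside the merged invariant regions.  Peaks straddling
a region boundary contribute area apportioned by overlap fraction
(area is a per-peak aggregate; a uniform-density apportionment is the
only assumption-free choice).  The smallest-AUC sample anchors at
factor 1.0, so all factors lie in (0, 1] and scaling never inflates
intensities.  If no invariant window exists the stage raises an error
rather than silently skipping normalization, since downstream cutoffs
would be meaningless.

*Background cutoff.*  After scaling, one cutoff for all samples is
selected from consistently highly expressed genes (above the
per-sample 95th expression percentile in every sample): the smallest
height `c` such that at least `cutoff_clean_fraction` (default 0.95)
of those genes have no H3K27me3 peak above `c` in their analysis
region.  Repressive marks at such genes are biologically implausible,
so remaining peaks there estimate the noise ceiling.  Note that the
"smallest such `c`" rule places the cutoff at a quantile of the
per-gene maximum noise height; with a clean fraction of 0.95 roughly
5 % of gene regions genome-wide can retain a just-above-cutoff noise
peak.  This is inherent to the selection rule, visible in the reported
achieved clean fraction, and the reason exact-recovery tests use the
generator's designed cutoff instead.  `cutoff_clean_fraction = 1.0`
trades a higher cutoff for a fully clean reference set.

H3K4me3 is a sharp mark whose peak caller output is assumed already
significance-filtered; its default cutoff is 0 (every peak counts),
with an override available.

## Gene marking and TSS profiles

A gene is marked when ≥ 1 above-cutoff peak overlaps its analysis
region by ≥ 1 bp — deliberately binary, matching how marked-gene
censuses are usually reported.  TSS profiles project peak heights onto
offsets around the TSS with all genes oriented 5′→3′; overlapping
peaks within one sample contribute the per-position **maximum** (summit
heights are not additive), and the per-position mean across genes is
binned (defaults: ±5 kb window, 50-bp bins; the window and bin are
free parameters since no canonical value exists).

## H3K27me3 profile classes

Regions per gene (transcription orientation): promoter (−3000, −100),
TSS (−100, +1000), broad (+1000, last exon).  Density is
`Σ height × overlap / region_length` over above-cutoff peaks, i.e.,
height-weighted coverage scaled to region size.  Decision rule, applied
in order to genes ≥ 4 kb:

1. Promoter if `d_prom ≥ 1.25 × d_tss` **and** `d_prom ≥ 1.25 × d_broad`
   (and `d_prom > 0`);
2. else TSS by the symmetric rule;
3. else Broad if ≥ 1 above-cutoff peak overlaps the broad region;
4. else Unclassified.  Genes under 4 kb are excluded as TooShort.

"25 % more" is read as the winner being ≥ 1.25× **each** competitor
(not their sum), with the boundary inclusive so the rule is
deterministic; both choices are configurable via `profile_margin`.
Densities use height × overlap rather than peak area so that a narrow
tall peak and a broad flat peak of equal area are distinguished by
where their mass sits.  Classification is invariant under multiplying
all heights (and the cutoff) by a constant.

## Bivalency dynamics

Mark states are a pure function of the two per-gene calls.  The gene
universe is the full gene-model table; genes absent from the
expression array still receive states (mark status is ChIP-only).
Transition tables conserve counts by construction (every row sums to
the origin-state census).  Trajectory labels over the four ordered
time points: `preexisting-retained` (bivalent at baseline and at
reoxygenation), `gained-retained` / `gained-lost` (acquired under
hypoxia, kept / reverted at reoxygenation), `never`, and `other`
(e.g., a lost preexisting state).  Reference-set overlap defaults to
`100 × |query ∩ reference| / |query|` — the convention when asking
"what fraction of our bivalent genes are known stem-cell bivalent
genes" — with a Jaccard option for symmetric comparisons.

## Expression integration

The detection floor is the **maximum** (not mean) log2 expression over
never-expressed control genes — a conservative ceiling on the
no-signal distribution.  "Expressed" means a per-time-point replicate
mean above log2(100) ≈ 6.6439 at one or more time points; the
replicate mean (not any single replicate) is used, as single-replicate
excursions are noise.  Differential testing runs two one-way
fixed-effects ANOVA models (hypoxia arm t0/t8/t24; reoxygenation arm
t24/+8 h/t0, the baseline serving as putative endpoint), BH-corrected
over expressed genes.  The fold-change gate is read literally as a
difference of ≥ 2 on the log2 scale (4-fold); `fc_log2_min` makes the
2-fold reading available.  Degenerate genes with zero within- and
between-group variance receive p = 1 (no evidence), zero within- but
nonzero between-group variance p = 0.  Group-median comparisons use
the unpaired two-sided Mann–Whitney rank-sum test: the compared gene
sets differ in size and membership, for which a signed-rank pairing is
undefined.  BH is the default FDR procedure with an optional
conservative Storey-π₀ rescaling; at these scales the two behave
identically for calling purposes.

## The synthetic-data generator

The generator emulates the *structure* of a two-mark, four-time-point
chromatin study of hypoxia and reoxygenation:

* **Genome/genes** — non-overlapping genes with lognormal lengths
  (median 8 kb, log-sd 0.6, clipped to [1.5, 60] kb) on the first 80 %
  of each chromosome, ≥ 12 kb apart so analysis regions never touch;
  sub-4-kb genes arise naturally and exercise the short-gene exclusion.
* **H3K4me3** — two peaks flanking the TSS of 46 % of genes with a gap
  directly over the TSS (nucleosome-free region); intergenic H3K4me3
  peaks are added so that 84 % of peaks are genic.  K4 status is held
  constant across time points: the modelled contrast is H3K27me3 gain
  at K4-premarked genes, the dominant route into bivalency.
* **H3K27me3** — 9 % of genes marked at baseline, split
  2 % / 2 % / 5 % across Promoter/TSS/Broad geometries (gene-body
  blanketing the majority class).  Promoter/TSS genes carry a dominant
  peak plus a weaker competitor peak whose density is exactly
  `class_margin`-fold lower (default 2.0), so classification at the
  1.25 margin is recoverable by design.  Under hypoxia 15 % of
  eligible K4-premarked genes gain a TSS-directed H3K27me3 profile at
  t8/t24 and 55 % of those gains persist at reoxygenation — fractions
  back-computed from a roughly threefold bivalency increase with about
  half of its excess retained.
* **Invariant domains** — ten shared 60-kb high-intensity domains with
  identical geometry in every H3K27me3 sample before distortion; their
  peak heights (60–90) sit well above the signal range (10–30) so the
  90th-percentile screen isolates them.
* **Distortion and noise** — each H3K27me3 sample's heights and areas
  are multiplied by a per-time-point depth factor (defaults 1.0, 0.8,
  1.3, 0.9); 3 000 noise peaks per sample lie strictly below the
  designed cutoff of 5 (in `hard_mode` the noise range doubles and
  overlaps the signal floor, for stress testing).
* **Expression** — per-gene log2 values are a state median (none 5.0,
  K4-only 9.0, K27-only 3.5, bivalent 7.5) plus a persistent per-gene
  baseline offset (sd 1.5) and replicate noise (sd 0.35, three
  replicates), reflecting that between-gene spread dominates replicate
  noise on arrays.  Offsets of H3K27me3-carrying genes are capped at
  +1.0 so the consistently-top-percentile population is free of
  genuine repressive signal — the premise of the cutoff validation.
  Sixty null genes at log2 ≈ 3.5 (sd 0.08) donate the detection
  floor.  A separate repeated-cycling fixture lowers
  bivalent-gained-retained genes by 0.75 log2 per condition step
  (baseline → 6 cycles → 18 cycles) while matched stably-K4-only genes
  hold their baseline.

**What it does not emulate:** read-level sampling noise (peak heights
are exact, so scale-factor recovery is near-perfect rather than
percent-level), peak-caller boundary jitter, replicate ChIP libraries,
correlated gene neighbourhoods, chromosome-specific composition, or
expression changes driven by anything other than mark state.  Passing
tests therefore demonstrate correctness of the *pipeline's inference
logic* under its stated assumptions, not robustness to every artefact
of real libraries; `hard_mode` probes the noise assumption
specifically.

## Numerical choices and degenerate inputs

* Height percentiles use linear interpolation (numpy default).
* Strictly-above comparisons everywhere a cutoff is applied: a peak at
  exactly the background cutoff is background.
* A sample with < 10 peaks cannot support a height percentile and is
  rejected.
* Density margins at exactly the threshold classify (≥, deterministic).
* An empty invariant-region set, a zero invariant AUC, an empty
  highly-expressed set, or an empty overlap query all raise errors
  naming the failing quantity rather than propagating NaNs.
* All generator randomness flows from one integer seed through named
  substreams (genome 0, peaks 1, expression 2, cycling fixture 3,
  null-expression 4), so stages are independently reproducible.

## Problem sizes

Default study: 2 000 genes on 8 × 10-Mb chromosomes, ~4 500–6 500
peaks per H3K27me3 sample, 2 000 null genes for calibration, chosen so
a full end-to-end run and the complete test suite finish in seconds on
one CPU while every designed effect remains well above its sampling
error (≥ 100 genes per compared group, ≥ 500 gained-bivalent genes in
the retention-recovery setting).

## Known limitations

* The background cutoff inherits a ~`1 − clean_fraction` false-mark
  rate by construction (see above); end-to-end marked-gene percentages
  run ~1 point above the designed fractions, and the end-to-end
  retention estimate is biased slightly low because noise-driven
  transient marks land in the gained-lost bin.
* The binomial window test is anti-conservative (basepairs within a
  peak are not independent); it is a screen, not an inference, and the
  all-samples intersection plus merging make the final regions robust.
* H3K4me3 normalization is not implemented beyond reusing the same
  machinery; the pipeline treats K4 peak files as pre-thresholded.
* No allele-level co-occurrence modelling: bivalency here means
  co-occurrence of the two marks at the same gene in the same
  population, as in peak-level data generally.
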
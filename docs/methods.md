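# Methods

This note documents the statistical model behind `lensepi`, the design
choices where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Coordinates and orientation

All internal coordinates are 0-based half-open; the GTF reader/writer is
the only ±1 conversion point in the code base. Group 1 is the lens
epithelial state and group 2 the fiber state; every log₂ fold change and
methylation difference is oriented fiber/epithelial, so positive
`diff_methyl` means hypermethylated in fiber cells. The
"Bismark-coverage-like" count dialect follows this convention too
(columns chrom, start, end, %, methylated, unmethylated with 0-based
half-open start/end), which differs from genuine Bismark coverage output
(1-based); hence "-like".

## DMR caller

The caller is a documented simplification of the DSS-style beta-binomial
approach for two-group WGBS comparisons, using the standard region
parameters (smoothing span 200 bp, site p < 10⁻⁵, delta 0, minlen 50 bp,
minCG 3, merge distance 100 bp, significant fraction ≥ 0.5). Equivalence
with DSS itself is *not* claimed: DSS's Bayesian shrinkage and smoothing
internals are replaced by explicit, testable components.

**Smoothing.** For site i and group g, μ̂ is the pooled proportion of
methylated reads over all CpGs within ± span/2 of i (window includes i),
summed across replicates. Sites where either group has zero reads in the
window are dropped (logged).

**Dispersion.** Per site, a method-of-moments estimate φ̂ is computed
from the replicate proportions within each group
(s² = μ(1−μ)·mean_j[(1+(N_j−1)φ)/N_j], ddof = 1) and averaged over
groups, clamped to [0, 0.99]. The genome-wide median φ̄ of the raw
estimates is the shrinkage target: φ\* = (kφ̄ + mφ̂)/(k + m) with prior
weight k = 10 pseudo-replicates and m the number of covered replicates at
the site. Sites with fewer than two informative replicates in both
groups receive φ̄. On simulated data this recovers φ = 0 (median
φ\* ≤ 0.003 at 50×, 3+3) and φ = 0.3 (median 0.31) and stays calibrated
under the null.

**Wald test.** The group difference of smoothed means is standardised by
the exact sampling variance of the pooled window estimator under the
beta-binomial model:

Var_g = Σ_{(i,j) ∈ window} N_ij² μ̂(1−μ̂)(1+(N_ij−1)φ\*)/N_ij / (Σ N_ij)²,

summed over every (site, replicate) read chunk contributing to the
window. Summing over window chunks — rather than only the replicates at
the tested site — matches the estimator the numerator actually uses;
with per-site totals alone the statistic would be so conservative that
moderate planted effects (Δ = 0.4 at 30×) would be undetectable at
p < 10⁻⁵. For an isolated CpG the two readings coincide
(e.g. μ̂₁ = 0.8, μ̂₂ = 0.2, one replicate of 100 reads per group, φ\* = 0
gives |wald| = 0.6/√0.0032 ≈ 10.61). p-values are two-sided normal
tails. If both groups have degenerate windows (variance 0) the site gets
p = 1 when the means agree and is excluded as unstable otherwise.

**Segmentation.** Consecutive significant CpGs chain while the half-open
gap between them (next position − previous position − 1) is below the
merge distance; the region runs from the first to the last chained
significant CpG and absorbs every intervening CpG. Span is inclusive
(last − first + 1), so three CpGs at 0/25/49 span exactly 50 bp and pass
minlen = 50. The significant fraction is evaluated after chaining. With
delta = 0 the site filter reduces to the p-threshold alone. This rule is
stated twice — once in the caller and once as a naive loop-based
reference — and the two are compared on thousands of random instances.

## Annotation

Feature categories are assigned by priority: promoter > 5′UTR > first
exon > first intron > other exon > other intron > 3′UTR > CGI > CGI
shore > repeat > intergenic. The ordering is this package's decision
(promoter first because promoter regions are the headline class); ties
across genes are resolved by the same priority. Promoters are the 2 kb
immediately 5′ of the TSS on the gene's strand, clipped to the
chromosome; an optional proximal (≤ 1 kb) / distal (1–2 kb) split is
available. CGI shores are the 2 kb flanks of each island. DMR-to-gene
links require ≥ 1 bp overlap with the promoter or gene body; a region
touching both features of one gene records the promoter.

The random-placement null resamples interval lengths from the observed
multiset (rather than using a fixed size, so the observed length
distribution is respected), places them uniformly over chromosome
lengths without any gap masking, and compares observed to expected
category counts with a Pearson goodness-of-fit χ², pooling categories
with expected count < 1. With 200 null draws per observed region the
self-null rejection rate at α = 0.05 is ≈ 0.05–0.06 (the residual
inflation comes from estimating the expected counts from finitely many
draws).

## Integration stages

DEG classes use strict inequalities (log₂FC > 0.4 or < −0.4 and
q < 0.05; boundary values are not differential; missing q means not
differential). Per-gene methylation change is the *unweighted* mean of
`diff_methyl` over in-scope regions (a CpG-count-weighted mean is
available but not default); genes whose average is exactly zero are
excluded from the quadrant table and counted separately. All χ² tests
are Pearson without continuity correction — with Yates' correction the
published promoter quadrant table ([[208, 58], [15, 30]]) would miss its
printed significance bound, while the uncorrected test reproduces both
printed bounds. Correlation p-values use the exact t-transform with
n − 2 df.

ATAC peaks are opening (log₂FC > 0, q < 0.05), closing (log₂FC < 0,
q < 0.05) or stable; q exactly 0.05 is assigned to stable so the classes
partition. Each DMR is matched to the single overlapping peak with the
most shared bases (ties: smaller q, then leftmost, then input order) so
each region is counted once. Triple sites are (region, gene) pairs, so a
region inside two DEGs' bodies contributes two sites; distinct-region
counts are reported alongside.

## Motif analysis

PWMs are log₂ odds with pseudocount 0.25 per cell against a zero-order
background estimated from the scanned sequences. Cell scores are
discretised to 0.01-bit bins and the exact distribution of the total
score under the background model is computed by convolving per-column
distributions; hit p-values are tail probabilities of this distribution
and agree exactly with brute-force enumeration on the same grid
(verified up to width 8, i.e. 4⁸ words). Scanning covers both strands
(reverse strand via the reverse-complemented matrix at forward
coordinates) with hit threshold p < 10⁻⁴.

Enrichment is a deliberate, documented replacement for AME's default
scoring ("default settings" do not pin down a reproducible method): per
motif, the number of primary vs shuffled-control sequences with ≥ 1 hit
is tested with a one-sided Fisher's exact test and BH-adjusted across
motifs. The default control is a per-sequence mononucleotide shuffle;
a dinucleotide (Euler-path) shuffle preserving all 16 adjacency counts
is available. Transcription factors are finally filtered by expression:
motifs whose TF gene (case-insensitive name match; heterodimer names
split on "::" and kept if either component passes) has total FPKM across
the two states below 1 are dropped; unmatched TF names are retained and
flagged.

## Synthetic generator

The generator emulates the *structure* of a two-state replicate study,
not its sequence biology. CpGs are planted explicitly by a renewal
process so the realised CpG set is exactly known and the per-bp CpG rate
is controlled; CGI-like segments get a 5× elevated rate. Non-overlapping
genes (2–6 kb, 1–6 exons, CDS-derived UTRs, both strands) are placed
with room for a full upstream promoter. Methylomes draw per-site,
per-replicate totals from Poisson(coverage) clipped to ≥ 1 and
methylated counts from a beta-binomial parameterised by (μ, φ) with
α = μ(1−φ)/φ, β = (1−μ)(1−φ)/φ (φ → 0 is exactly binomial). Planted
regions shift group 2's μ by ± the effect size, clamped to [0.02, 0.98];
signs are balanced 50/50 by default (the real study is hyper-dominated,
but a symmetric default measures power for both directions;
`hyper_fraction` tunes it). Planted regions are anchored on CpGs, kept
≥ 500 bp apart (so calls stay distinct) and required to contain at least
`dmr_min_cpgs` CpGs — reported DMRs overwhelmingly lie in CpG-bearing
regulatory context, and a region without CpGs is undetectable by
definition.

Expression tables couple log₂FC to each gene's true average planted
effect through a linear slope plus Gaussian noise; FPKMs are
back-computed from a log-normal epithelial baseline; q-values are
truth-linked (genes with |log₂FC| > 0.4 are significant with
probability 0.9) because the differential-expression fit itself is out
of scope. ATAC tables put one differential peak over each planted region
(log₂FC coupled to the planted effect) plus stable background peaks.

Because selecting DEGs (|log₂FC| > 0.4) changes the realised
correlation, "coupling targeting r" is defined on the selected set:
`calibrate_expression_noise` solves for the noise SD by bisection on a
large fixed-seed resample of the generator's own truth column with the
DEG filter applied. The accessibility side has no such selection, so
`calibrate_atac_noise` uses the closed form
σ = |slope|·Δ·√(1/r² − 1).

## Validation experiments and their scope

`lensepi.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) fixes the study conditions once:

* coupling recovery on an 18 Mb genome, 1900 genes, 1800 planted regions
  (Δ = 0.4, φ = 0.1, 30×, 3+3), targets r = −0.4 (expression, ≈ 1000
  selected genes) and r = −0.86 (accessibility);
* caller power on 150 planted 200 bp regions (Δ = 0.4, 30×, 3+3,
  φ = 0.1, CpG-dense placement): sensitivity ≈ 0.94–0.99 at ≥ 50 %
  reciprocal overlap, false-discovery fraction ≤ 0.02;
* a null methylome with > 2×10⁵ CpGs: ≤ 1 call per 10⁵ CpGs;
* exact agreement with naive references for segmentation, annotation and
  overlap matching on 1000 random instances each;
* PWM enumeration, null calibration (200 repetitions), planted-motif
  recovery, and byte-identical summaries across same-seed runs.

Problem sizes were chosen so the full suite runs in minutes on one CPU.
These experiments show the pipeline recovers what the generator planted;
they do not show the generator reproduces real lens methylomes. In
particular the generator omits read-level artefacts and bisulfite
conversion error, non-CpG (CHG/CHH) methylation, spatially varying
baseline methylation, genuine q-value estimation, and sequence realism
of repeats; the published genome-scale counts and correlations can only
be reproduced from the deposited sequencing data.

## Other numerical choices

* Methylated-cytosine definition for context proportions: pooled
  methylated reads ≥ 1 (configurable) — no published threshold exists.
* Dispersion shrinkage weight k = 10: small enough to let 6 replicates
  dominate, large enough to stabilise single-site estimates.
* Random-null chromosome choice is length-weighted; draws longer than
  the chosen chromosome are redrawn (capped, then error).
* Zero-variance Wald sites: p = 1 when group means agree, excluded
  otherwise.
* Enrichment background frequencies are estimated jointly from primary
  and control sets.
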
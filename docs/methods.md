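# Methods

This note documents the models, defaults and design choices behind
`t3enh`, and what the synthetic validation does and does not establish.

## Differential acetylation model

Region tag counts are modelled as negative binomial,
`K_ij ~ NB(mean = s_j q_ig, dispersion alpha_i)`, for region `i`,
sample `j` in group `g`, with per-sample size factors `s_j`.

**Size factors.** `median_ratio_size_factors` implements the
median-of-ratios estimator (per-column median of count over row
geometric mean, rows with zeros excluded, no renormalization) and is
the default when no factors are supplied. The pipeline passes
sequencing-depth factors (`lib_size / 1e7`) for ChIP contrasts instead:
the study design plants ~26% of regions responding in one direction,
and a data-driven median-of-ratios is measurably biased when so large
an asymmetric fraction changes (we observed a −0.4 shift in log2FC,
enough to push true 4-fold regions under the log2FC > 1 threshold).
Depth normalization is also what standard tag-count quantification
does. RNA contrasts keep the median-of-ratios default, as induction
and repression partially balance.

**Dispersion.** Per-region method of moments on normalized counts,
using the within-group variance pooled across the two groups:
`alpha_i = (v_within − m_i * mean(1/s)) / m_i^2`, floored at 1e-8.
With two replicates per group this estimator has roughly one degree of
freedom of information; plugging it straight into a Wald test yields a
type-I error near 0.16 at nominal 0.05. We therefore moderate it by an
abundance trend — the mean of the per-region estimates within each of
20 abundance-rank bins — and clamp the per-region value to
`[trend, 2 * trend]`. Measured on the null simulation (5000 regions,
baseline mean 100, dispersion 0.05, 2+2 samples, ±30% library jitter)
this gives a fraction of p < 0.05 of ~0.040, zero regions passing
q < 0.01 ∧ log2FC > 1, and 0.99 per-mark power on planted 4-fold
regions. The clamp (rather than the trend alone) leaves room for
genuinely overdispersed regions; the upper bound of 2 is a compromise
between robustness to heterogeneous dispersion and not destroying
power through the estimator's own sampling noise. There is no
dispersion shrinkage toward a fitted curve, no LFC shrinkage, no
independent filtering and no outlier replacement; downstream decisions
use only (log2FC, FDR) thresholds, which these refinements would not
change qualitatively.

**Test.** log2FC is `log2(m_trt + c) − log2(m_ref + c)` with
pseudocount `c = 0.5` (configurable), the Wald standard error comes
from the delta method on the NB variance of each group mean, p-values
are two-sided normal, and BH adjustment is applied per contrast and
per mark separately. Groups with zero total counts are reported via
the pseudocount and flagged `degenerate`.

## Exact tests

`fisher_exact_2x2` computes the conditional two-sided p — the sum of
hypergeometric probabilities of tables (at fixed margins) whose
probability does not exceed the observed table's — entirely in integer
arithmetic: probabilities share the denominator `C(n, c1)`, so the
inclusion rule compares integer numerators and the final p is one
exact rational. This removes floating-point ambiguity at ties, which
matters because symmetric margins produce exactly tied tables. Odds
ratio is `ad/bc`, with 0/∞ flagged `extreme`.

`wilcoxon_signed_rank` drops zero differences, midranks ties,
enumerates the exact sign-flip null below 25 remaining pairs (a
convolution over doubled ranks, so midranks stay integral; two-sided p
by symmetric deviation from the mean) and otherwise uses the
tie-corrected normal approximation with continuity correction.

## Region calling

Calling operates on binned tag tracks. In region mode, sliding 1 kb
windows (step = bin size) are tested against the genome-wide Poisson
expectation at p < 1e-4 and significant windows merge when separated
by less than 2500 bp (strict); in factor mode, 200 bp windows are
selected greedily as non-overlapping local maxima. The Poisson window
test is this package's explicit replacement for the unspecified
enrichment model of the original peak-calling tool; the window size,
merge distance and style-mode semantics follow the tool's flags.
Differential significance is increase-only (hyperacetylation is the
object of study); decreases are reported but never flagged.

## TRBS tertiles

TR-bound hyperacetylated regions are ranked by replicate-averaged,
depth-normalized HDAC3 tag density in the hypothyroid condition
(descending, ties broken by coordinate) and split into tertiles of
floor(n/3), with the remainder's extra site going to the top tertile
when n mod 3 = 2. Top tertile = type 1A (poised), bottom = type 1B
(established). The ±500 bp quantification window around the TRBS
centre and the replicate-averaged ranking are this package's choices;
the classification is invariant to any common positive scaling of the
densities.

## Super-enhancers

Peaks stitch by transitive closure of "gap < 12,500 bp" (the common
stitching convention, consistent with constituent spacing of
10–15 kb). With signals sorted ascending and normalized
(`x = rank/n`, `y = signal/max`), the cutoff index is
`argmin(y − x)` — the discrete restatement of the tangent-of-slope-one
rule — and everything above it is a super-enhancer. Co-occupancy
enrichment draws `n_random = 600` acetylated regions (without
replacement, test regions excluded, seeded) and applies the Fisher
exact test; one draw per test, no averaging over draws.

## Hi-C

Contacts are binned at 5 kb and quantified as the summed counts over
the bin pairs covered by a 10 kb window around each anchor midpoint.
The background of a pair is the "opposite direction" contact: the
downstream anchor's bin set is reflected about the upstream anchor's
bin span (`j → min(A) + max(A) − j`), which preserves the multiset of
bin distances, so on any translation-invariant matrix the background
equals the observed count exactly — this symmetry is asserted in the
tests. If the mirror leaves the chromosome the other anchor is
reflected instead (flagged); pairs with neither mirror on-chromosome
are excluded. Loop detection screens all same-chromosome region pairs
within [50 kb, 2 Mb], comparing the observed window count to the
distance-decay expectation (mean count per log-spaced distance bin,
linearly interpolated) with an observed > 2×expected filter and a
Poisson upper-tail threshold of 1e-5. Matrix balancing and TAD calling
are out of scope; TADs are an input, and regions are assigned to the
TAD containing their midpoint.

## Gene linkage

RPKM is `count / (exonic_kb) / (library_millions)`. Genes link to
hyperacetylated regions whose nearest base lies within 100 kb of the
TSS (inclusive; 0 if the region spans the TSS; one TSS per gene).
Fold enrichment of an outcome in a gene set is the observed fraction
over the mean fraction in ten seeded draws of 1000 random genes, with
a two-sided one-sample t-test of the ten random fractions against the
observed fraction (the "n = 10" reading of the design).

## Synthetic data generator

The generator is the package's study system. Defaults: 3 chromosomes
of 20 Mb; 2000 non-overlapping regions (minimum gap 5 kb except inside
SE clusters) in classes type1A 10%, type1B 10%, indirect_SE 3%,
indirect_loop 3%, constitutive 24%, null 50%; NB counts with baseline
mean 100, background 5, dispersion 0.05; acetylation fold 4
(hyper/hypo) at responsive classes; HDAC3/NCOR1 drop 3-fold at type 1A
sites with hormone; TR/CBP/MED1/DNase recruit 5-fold at type 1B sites;
library-size jitter ±30% (log-uniform); two ChIP replicates, four RNA
replicates. TADs tile each chromosome in 0.5–2 Mb blocks; 35% are
"hormone-active" and receive every TR-bound unit, SE cluster (5–10
constituents spanning ~12 kb, each containing one indirect_SE member
and one TR-bound member) and loop pair (anchors 200–800 kb apart in
one TAD) — without this concentration a genome this dense would place
nearly every region in a TRBS-containing TAD and the TAD-confinement
contrast would be unmeasurable. Hi-C is Poisson around
`20 / (1 + d/50 kb)` per bin pair within a 2 Mb band, with planted
loop anchors boosted 6-fold. Genes: 15% induced (4-fold, each driven
by a hyperacetylated region 10–80 kb away), 10% repressed (placed
> 100 kb from any hyperacetylated region so the induced-vs-repressed
linkage contrast reflects planted structure), the rest null; half of
the type1A-driven induced genes are NCOR1-dependent (3-fold up in the
corepressor-disruption genotype), none of the type1B-driven ones,
mirroring the expectation that corepressor loss derepresses poised
sites. One RNG stream per layer (placement, ChIP counts, Hi-C, RNA),
each derived from the single seed, keeps layers independently
reproducible; identical seeds give byte-identical outputs.

What the generator does **not** emulate: read-level artefacts (GC,
mappability, duplicates), fragment-size effects, partially overlapping
peak boundaries between marks, dispersion heterogeneity across
regions, trans contacts, unbalanced Hi-C coverage, isoform structure,
and any motif-level sequence content. Passing recovery tests therefore
demonstrates the pipeline's logic and calibration under the stated
count model, not robustness to every artefact of real libraries.

## Null self-consistency of the resampling tests

When the "test" regions are themselves drawn from the acetylated-region
pool, the SE co-occupancy and TAD-confinement Fisher p-values should be
uniform. Exactly symmetric group sizes create exact probability ties
(tables `a` and `K − a` have identical probability), coarsening the
discrete null; the validation therefore draws unequal sizes (600 test
vs 900 random), where the exact test's residual discreteness is small
(KS distance ~0.04 from uniform). The median odds ratio over 200
seeded draws is checked against 1.

## Numerical and degenerate-input choices

- Overlap means ≥ 1 bp shared; coordinates are 0-based half-open; BED
  on disk, 1-based display only at boundaries.
- Merging/stitching gaps are strict inequalities (a gap of exactly the
  threshold separates).
- All-equal stitched signals: no super-enhancers, with a warning.
- Fewer than 3 TRBSs: all mid tertile, with a warning.
- Constant rows z-score to zeros; NaN p-values propagate through BH
  without counting toward m.
- Empty inputs return empty outputs of the right shape rather than
  raising, except where the operation is undefined (no all-positive
  row for size factors; trans anchors for contact quantification).
- Every resampling call takes and records a seed; the pipeline fans a
  single run seed out to fixed per-stage offsets.

## Problem sizes used in validation

The shipped validation runs the default synthetic study (2000 regions,
3×20 Mb, 1500 genes), a 5000-region null/power simulation for the NB
test, 200 seeded draws for the resampling nulls, and exhaustive
enumeration of all 2×2 tables with margins ≤ 30 for the Fisher oracle.
These sizes give stable pass/fail margins for every threshold tested
(recovery ≥ 0.90/0.85/0.80 with observed values ≥ 0.93/1.00/0.88
across seeds) while keeping the full suite under a minute of compute.

## Known limitations

- The NB test supports two-group contrasts only; no GLM designs or
  continuous covariates.
- The dispersion clamp assumes dispersion varies smoothly with
  abundance; datasets with strongly bimodal dispersion at fixed
  abundance would be tested anti-conservatively above twice the trend.
- Loop detection's expected-decay curve is fit on the full band of the
  matrix including planted loops; with many strong loops the
  expectation would inflate slightly (negligible at the planted
  density).
- The acetylated-region universe for resampling is the full region
  set; promoter exclusion and input subtraction are not implemented.
- One TSS per gene; multi-isoform resolution is upstream.
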
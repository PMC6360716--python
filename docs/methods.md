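# Methods

## Overview

`crosspath` estimates, for a set of traits with GWAS summary statistics,
(i) per-pathway association p-values from two complementary enrichment
engines, (ii) a combined per-pathway p-value via Fisher's method, and
(iii) pairwise trait–trait association from the overlap of significant
pathway sets. Everything operates on summary statistics plus an external
LD reference; no individual-level phenotype data are used.

## Gene scoring engine

**Model.** Under the null, GWAS z-scores of nearby SNPs are asymptotically
jointly Gaussian with covariance equal to the LD correlation matrix R of
the SNPs in the population. For a gene window with p-values p₁…p_m, the
score is T = Σᵢ F⁻¹_{χ²₁}(1 − pᵢ) = Σᵢ zᵢ², whose null law is the weighted
sum Σⱼ λⱼ χ²₁ with λ the eigenvalues of R. R is estimated as the Pearson
correlation of dosages in the reference panel; eigenvalues below 1e-8 are
clipped to zero (trace is preserved to ~1e-6 relative).

**Windows.** SNPs map to a gene if within ±50 kb (`window_bp`) of its TSS
(strand-aware: BED start for `+`, end for `−`). A SNP may belong to
several windows; genes without SNPs are untested.

**Evaluating the tail.** The survival function of Σλⱼχ²₁ is computed by
Imhof's inversion formula,
P(Q > x) = 1/2 + (1/π)∫₀^∞ sin θ(u) / (u ρ(u)) du, evaluated by Simpson's
rule on a grid scaled to the integrand's oscillation frequency
(~16 points per period up to the point where the envelope 1/(u ρ(u))
drops below 1e-8), plus an integration-by-parts correction for the
truncated oscillatory tail. This agrees with adaptive quadrature to ≤1e-5
relative over random weight vectors at ~1 ms per evaluation. Equal weights
(identity LD, rank-one LD) are handled in closed form as a scaled χ².
Below p ≈ 1e-7 — where the inversion's absolute error floor dominates —
the Liu–Tang–Zhang four-moment non-central-χ² approximation takes over;
Satterthwaite matching (scale = Σλ²/Σλ, df = (Σλ)²/Σλ²) is the fallback if
the inversion cannot be evaluated. Input p-values of exactly 0 are clipped
to 1e-30 with a warning so quantiles stay finite.

**Pathway aggregation.** Member genes whose windows overlap on the same
chromosome are fused into one meta-gene and re-scored jointly over the
union of their SNPs, preventing shared LD from being counted as
independent evidence. The pathway statistic is Σ over units of
F⁻¹_{χ²₁}(1 − p_unit), referred to χ² with df = number of units. Pathways
with no scored member gene are reported as missing (untested), never as
p = 1.

**SNP prefilter.** A nominal-significance prefilter (`snp_p_max`, retention
inclusive at the bound) is available for compatibility with pipelines that
score only SNPs at p < 0.01, but it truncates the null and inflates gene
scores, so the default scores all MAF-filtered SNPs and the prefilter logs
a warning when enabled.

## Interval enrichment engine

**Clumping.** Greedy, index-based (standard plink semantics): the most
significant unassigned SNP (p ≤ 0.01; ties by position then id) seeds a
clump that absorbs every unassigned significant SNP within 1 Mb and with
r² ≥ 0.2 *to the index* (single linkage to the index, not between
members). The interval is the span of clump member positions. By
construction every significant SNP lands in exactly one clump, and index
SNPs of distinct intervals on one chromosome are separated in r² or
distance.

**Statistic and null.** E = number of intervals overlapping ≥ 1 member
gene (each interval counts once; gene padding defaults to 0 bp and is
configurable). The null resamples, per replicate, one placement per
observed interval: proposals are anchored at a SNP drawn uniformly from
the summary-statistics map with a uniform offset (uniform-position
proposals cannot satisfy the SNP-count match for 1-bp single-SNP
intervals), and accepted when length is within ±20% (relative),
overlapping-gene count matches exactly, and contained-SNP count is within
±20%. After 1,000 rejections the tolerances double once; if that also
fails the observed placement is reused with a warning. The same replicate
(a genome-wide null set) is scored against every pathway, and
p = (1 + #{E_null ≥ E_obs}) / (R + 1).

**Conservatism.** E is a small discrete count; on null data most pathways
have E_obs = 0 and the null distribution carries heavy tie mass, so the
empirical p is super-uniform (P(p < α) ≤ α at every α, with e.g.
P(p < 0.05) ≈ 0.02 on the bundled null fixture) rather than exactly
uniform. This is inherent to permutation p-values of discrete statistics
and is the behaviour the tests assert; the matched sampling itself is
unbiased (mean E_null ≈ mean E_obs).

## Combination and cross-trait association

Fisher's method merges the two engines per pathway:
χ²₄ = −2(ln p₁ + ln p₂). Cells with only one engine's p-value keep it but
get no combined value (one-engine and two-engine evidence are never
mixed); a `robust` flag additionally marks pathways significant in both
engines at α. Significant sets are {pathway : p_combined < 0.01} (strict).
For each trait pair the universe N is the set of pathways tested
(non-missing combined p) in *both* traits, the 2×2 table is tested with a
one-sided (enrichment) exact hypergeometric tail, and BH adjustment runs
over all tested pairs. Networks are emitted at adjusted p < 1e-3 and
< 0.01 (edge weight −log₁₀ adjusted p, label = shared count, isolated
nodes kept). MDS is classical (Torgerson double-centering) on the distance
1 − ρ, ρ the Spearman correlation of −log₁₀ p_combined profiles
(pairwise-complete); clustering is Ward linkage on the same Spearman
distance applied to rows of the symmetric FET p matrix (diagonal = minimum
observed p; constant rows get distance 1 with a warning), exported as
Newick with merge heights as branch lengths.

## Pathway collection hygiene

Collections are restricted to 10–200 genes (inclusive) and pruned to
pairwise overlap ≤ 30%, where overlap = |A∩B| / max(|A|,|B|) and the
*smaller* pathway of a violating pair is removed. Violating pairs are
resolved highest-overlap-first with deterministic tie-breaks (equal sizes:
remove the lexicographically later name), iterated to a fixed point, so
the output is idempotent and independent of input order. Gene identity is
exact string match after uppercasing and whitespace stripping.

## Synthetic data

The generator emulates the statistical structure of consortium inputs:

* **Panel.** Dosages arise from a latent Gaussian AR(1) copula within
  blocks of consecutive SNPs, thresholded at Hardy–Weinberg genotype
  quantiles of MAFs drawn U(0.05, 0.5) (the analysis filters MAF < 0.05,
  so fixtures start above it; the filter itself is tested on hand-built
  records). Thresholding attenuates correlation, so the latent coefficient
  of each adjacent pair is calibrated by bisection against the exact
  bivariate-normal dosage correlation (Drezner–Wesolowsky quadrature) to
  hit the requested dosage r; very mismatched MAF pairs that cannot reach
  the target even at latent ρ = 0.999 are clipped. Sites whose empirical
  MAF falls below 0.05 are re-thresholded at a higher frequency on the
  same latent, preserving LD.
* **Summary statistics.** Null z-scores are drawn with covariance exactly
  the panel's empirical correlation, by projecting one white-noise sample
  per panel individual through the standardised dosage matrix — this makes
  the generator's null agree with the gene-score engine's null everywhere,
  including across block boundaries. Causal signal shifts the z-score mean
  by `effect_size` for a per-gene fraction of SNPs inside the windows of
  genes belonging to the trait's causal pathways; p = two-sided normal
  tail. Because one noise vector is shared across SNPs, the *per-trait*
  fraction of significant SNPs fluctuates more than binomial; calibration
  statements hold on aggregate over traits.
* **Annotations.** Genes occupy one slot each on an even per-chromosome
  grid (never overlapping); pathways sample genes without replacement with
  sizes uniform in a requested range.

**What the synthetic data does not model:** population structure,
imputation error, recombination-map heterogeneity, rare variants, the X
chromosome, gene-density clustering, or realistic pathway overlap
topology. Passing tests therefore demonstrate the statistical machinery —
calibration of the nulls and recovery of planted signal — not performance
on any real trait.

## Benchmark problem sizes

The bundled experiments (`crosspath.experiments`) use desk-scale fixtures
chosen as the package's standard validation conditions: the null
calibration uses 500 panel samples and 5,000 SNPs (2 chromosomes, 5 kb
spacing, blocks of 20 at dosage r = 0.7) with 500 genes × 10 null traits;
the recovery benchmark uses 2 × 25 Mb at 10 kb spacing, 400 genes sparse
enough that ±50 kb windows of neighbouring genes do not overlap
(otherwise planted signal bleeds between genes and saturates every
pathway), 200 pathways of 10–15 genes, 5 planted pathways at effect 6 on
half the window SNPs, and 200 interval-null replicates (the pipeline
default is 1,000).

## Known limitations

* The gene-score engine implements the sum-of-quantiles statistic only; a
  max-SNP variant is out of scope, as is special handling of the MHC
  region or gene fusion across chromosomes.
* The interval engine's second-stage multiple-testing permutation (as in
  some interval-enrichment tools) is not implemented; only per-pathway
  empirical p-values are produced.
* FET treats pathways as exchangeable units; residual inter-pathway
  correlation (overlap ≤ 30% is not zero) makes the pairwise test slightly
  anti-conservative in principle, mitigated by the pruning step.
* Combined p-values assume the two engines are independent given the
  null, which is approximate since both consume the same summary
  statistics.
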
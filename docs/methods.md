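# Methods

This note documents the models, conventions and numerical choices behind
`toxassoc`, and what the synthetic-data generator does and does not emulate.

## Phenotype model

Toxicity is recorded as NCI-CTC grades 0–4 per symptom. Composite outcomes
(DMN, DM) take the **maximum grade over their constituent symptoms** before
dichotomization — the standard "any severe constituent" toxicity convention;
per-cycle timing is collapsed to the maximum over the observation window.
Samples outside an outcome's treatment subgroup (DM/HFS/severe-HFS are
Capecitabine-only) are *excluded*, not counted unaffected; samples missing a
required grade are *missing*. Grade 4 HFS, never observed in the motivating
cohort, would map to affected for both HFS outcomes.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not
a facsimile of real human data.

* **Genotypes.** Ancestral MAFs are Beta(0.25, 2.5) scaled to
  [0.001, 0.5] — heavily right-skewed, so most variants are rare, as on an
  exome array. Subpopulation frequencies follow the Balding–Nichols model at
  a configurable F_ST (default 0.005, two subpopulations mixed 60:40 —
  mild within-continent structure). Outside LD blocks, genotypes are
  binomial draws within subpopulation, hence Hardy–Weinberg-consistent.
* **LD blocks.** Each block draws two haplotypes per individual from a
  finite pool (default 20 haplotypes) whose haplotypes come from a latent
  Gaussian AR(1) (lag correlation 0.9) thresholded at the allele frequency:
  marginal frequencies are preserved while adjacent-SNP r² > 0 with
  realistic decay, and genotypes are always valid. Region blocks are placed
  across chr6:29,600,000–33,100,000 (the conventional MHC span, 1-based
  closed) as a stand-in for the HLA. `CohortSpec.study_scale()` reproduces
  the study's dimensions (504 samples, 59,277 variants, ~2.3k region SNPs).
* **Batches/treatment/demographics.** Two batches in the study's 73.5:26.5
  ratio; Capecitabine fraction 254/504; ~60% male; age ≈ N(63, 11.5).
* **Grades.** Each symptom has a latent liability = Σ β_v·(g_v − ḡ_v) +
  ancestry term + N(0,1) noise, cut at fixed thresholds into grades 0–4.
  The default thresholds are calibrated analytically so the four
  dichotomized outcomes hit the motivating study's margins under
  independent liabilities: severe diarrhoea = mucositis = 1 − √(1 − 50/249),
  severe neutropenia chosen so the three-symptom composite hits 133/502,
  and HFS grade ≥ 2 / = 3 at 36/254 and 13/254. Sub-severe grade
  probabilities (e.g. P(grade ≥ 1) = 0.55 for diarrhoea) are not constrained
  by the study's published counts and were fixed once at plausible values.
* **Planted effects.** Per-variant liability effects, an ancestry effect,
  and a region effect (n causal SNPs spread evenly over the region). The
  region-effect default used by the power checks — 20 causal SNPs at
  β = 0.6 per allele on the DMN liabilities — is the calibrated point at
  which the enrichment test reaches ≥ 80% power at the scaled test
  dimensions (200 samples, 300-SNP region, 500 permutations) while the null
  configuration rejects at ≈ 5%.

**What it does not emulate:** real human haplotype structure and allele
frequency spectra, imputation error, genotype-calling artefacts
(intensity-level effects), batch effects on genotypes, linkage between the
region and the rest of the genome, and correlated symptom liabilities.
Passing tests therefore certify the statistical machinery under its stated
assumptions, not performance on any particular real cohort.

## QC conventions

* **HWE exact test:** mid-p-less, two-sided by probability ordering; ties in
  "probability ≤ observed" use a 10⁻¹⁰ relative tolerance; monomorphic
  input returns 1. Distributions are cached per (n, rare-allele count), so
  exhaustive sweeps are cheap.
* **Thresholds:** variants retained at call rate ≥ 0.99 *and* HWE p > 10⁻⁶;
  samples retained at call rate strictly > 0.97 (the two phrasings are read
  literally). Filter order: variant filters → sample filters → relatedness →
  carrier exclusion; each step is recorded in a `QCReport` whose dimension
  chain reconstructs the input.
* **Relatedness:** method-of-moments P(IBD=k) from IBS counts with
  expectations at sample allele frequencies, no finite-sample bias
  correction (adequate for the duplicate/first-degree/unrelated distinctions
  it must make); PI_HAT ≥ 0.4 flags first-degree-or-closer pairs, and the
  lower-call-rate member is removed. Pairs are rescaled for per-pair
  missingness by their called fraction.
* **Carrier exclusion:** a missing genotype at a listed risk variant counts
  as non-carrier — exclusion requires observed copies.
* **Batch concordance:** 2×2 allele-count χ² per variant between the two
  largest batches plus point-biserial correlation of the first 5 PCs with
  batch membership.

## PCA

Missing genotypes are mean-imputed per variant before standardization by
√(p(1−p)) at the sample allele frequency; scores are eigenvectors of the
sample–sample covariance, with a deterministic sign convention
(largest-magnitude loading positive) so repeated runs agree exactly.
Pruning defaults: MAF > 0.01, 50-SNP windows, step 5, r² ≤ 0.5 (the
ubiquitous defaults; all config-exposed). Outlier SDs and medians are
recomputed on each iteration's retained samples.

## Association

* Logistic fits use statsmodels; separation or non-convergence flags the
  variant (no finite OR reported) and excludes it from λ, whose denominator
  is the exact 1-df χ² median 0.45493642…; λ needs ≥ 100 valid statistics.
* Per-variant missing-genotype handling is complete-case.
* SKAT weights MAFs on the analysed (case+control) sample; the MAF < 0.05
  gene-set bound is strict; a variant annotated to two genes enters both.
* The mixture-of-χ² survival function is computed by Imhof's inversion
  integral, split into a directly integrated head [0, a] and an oscillatory
  tail handled by QUADPACK's sin/cos (QAWF) weights at frequency Q/2 —
  this is orders of magnitude faster than naive infinite-interval
  quadrature and equally accurate (validated against Monte-Carlo in the
  suite). A single eigenvalue short-circuits to the exact scaled-χ²; the
  Liu–Tang–Zhang moment-matched non-central χ² is the recorded fallback.
* **Small-sample caveat:** the mixture null is asymptotic. At n ≈ 60 the
  analytic SKAT/CMC p-values track a phenotype-permutation null only to
  within a few percent absolute (the suite measures this); gene-level
  p-values from cohorts of this size should be interpreted accordingly, or
  verified by permutation.

## Region enrichment test

Default per-SNP statistic is the allelic 2×2 χ² without covariates — the
most literal "sum of chi-squared association statistics" — with a
covariate-adjusted logistic score statistic selectable. Phenotype labels
are permuted jointly against genotypes and covariates (case count
preserved); the observed pass and every permuted pass share one
byte-identical variant inclusion list (variants testable under the observed
labelling). Ties count as exceedance in the empirical p; the (k+1)/(n+1)
estimator is available but off by default. Permutations are vectorized as
matrix products over batches of label vectors, so 10,000 permutations over
a few hundred SNPs take well under a second.

## Power and sample size

The allelic (2N chromosomes) model compares risk-allele frequency between
cases and controls with the case frequency induced by the per-allele OR:
p₁ = OR·p/(1 − p + OR·p). The default computation **enumerates the joint
binomial distribution of case/control allele counts** (support truncated at
±12 SDs) and accumulates the probability that the Pearson allelic χ²
exceeds its critical value. This is the power of the test actually
performed and matches simulation by construction; the classic two-proportion
normal approximation (pooled SD under H₀, unpooled under H₁) is available as
`method="normal"` but understates the discrete power by a few percent in
this regime, while pooled-NCP variants overstate it. Sample-size search is
bisection bracketed by the normal approximation, refined downward to the
smallest N meeting the target (monotone up to allele-count rounding).
OR = 1 returns α exactly by convention. For the headline design point
(MAF 0.05, OR 3, α = 8.4×10⁻⁷, case fraction 133/502, power 0.80) the exact
method returns N = 806; a balanced 1:1 design would need ≈ 750.

## Problem sizes

The suites run at desk scale by design: permutation calibration uses 500
cohorts of 200 samples × 300 region SNPs at 500 permutations; power uses 50
replicate cohorts; gene-level calibration uses ~1,000 genes over 5,000
mostly-rare variants in 400 samples; the HWE oracle sweep is exhaustive to
n = 200. Defaults in the library itself (10,000 permutations,
study-scale cohort dimensions) remain those of the motivating design.

## Known limitations

Dominance and epistasis are absent from both generator and tests (additive
dosage throughout); the relatedness estimator is uncorrected for small
reference samples; HLA imputation is consumed, never performed (marker
matrices stand in for imputation output); no Tracy–Widom significance for
eigenvalues; no projection onto external reference panels; the CLI is a
thin convenience layer, not a workflow manager.
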
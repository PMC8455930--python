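# Methods

`mtgrs` implements a complete multi-trait genomic risk-score (MT-GRS)
workflow for a case-control focal disease with correlated information
traits: marginal GWAS, LD-score regression for genetic parameters,
selection-index re-weighting of marker effects, clumping-and-thresholding
score construction, and incremental Nagelkerke-R² evaluation.  This note
records the model, the defaults, and the design choices that were genuinely
open.

## Model and procedure

**Marginal association.**  For each marker j the model is
`y ~ intercept + covariates + allele count_j`, fit by ordinary least squares
(quantitative traits) or IRLS logistic regression (binary traits; deviance
tolerance 1e-8, max 50 iterations).  Missing genotypes are handled by
per-marker sample exclusion.  Wald tests: t tail for linear fits, normal
tail for logistic.  Markers that are monomorphic after exclusions or whose
IRLS does not converge are flagged invalid and excluded downstream.  The
fits are batched across markers (shared covariate block, per-marker normal
equations solved with stacked 4×4 solves), which is why a 5,000-marker scan
over thousands of samples takes seconds rather than minutes.

**Bias-adjusted LD.**  Pairwise linkage disequilibrium uses the adjusted
squared Pearson correlation `r~2 = r2 − (1 − r2)/(N − 2)`, which removes the
upward finite-sample bias of r²; for unlinked markers its expectation is
~0, so windowed LD-score sums are unbiased regardless of window length.
The LD score of marker i sums r~2 over a window of `window` markers centred
on i (default 5,000, i.e. ±2,500), truncated at chromosome boundaries,
including the self term exactly 1.  The reference panel is the training
genotypes themselves.  For windowed computations genotypes are mean-imputed
before standardization (per-entry missingness is small by design); the
two-column `adjusted_r2` primitive uses pairwise-complete samples.

**Heritability and genetic correlation.**  With squared z-scores
`y = (β̂/se)²` and regressor `Z = n_eff · l/m`, the heritability estimator
is the no-intercept least-squares slope of y on Z; the genetic correlation
regresses the z-score product of two traits on `√(n₁n₂) · l/m` and rescales
by `√(h²₁h²₂)`.  `n_eff = median 1/(2·af·(1−af)·se²)`.  Binary-trait
heritability on the observed scale converts to the liability scale by
`h²_liab = h²_obs · K(1−K)/φ(Φ⁻¹(1−K))²` at prevalence K.

Three intercept behaviours are provided, because the literal no-intercept
form is not identified in finite samples:

* `intercept=False, baseline=0` (default): the literal regression.  Under
  the null E[χ²] = 1, so this slope absorbs the unit baseline and is biased
  upward by ≈E[Z]/E[Z²]; it is exact for noiseless constructed inputs and is
  kept as the reference form.
* `baseline=1.0`: the known null level is subtracted from y before the
  no-intercept solve (for the z-product regression, the analogous offset is
  `n_overlap·r_pheno/√(n₁n₂)` — for fully overlapping samples simply the
  phenotypic correlation, which the pipeline computes from the training
  cohort).  This constrained-baseline estimator is unbiased and markedly
  more precise than freeing the intercept, because the χ² statistics of
  markers in the same LD block are strongly correlated and the free
  intercept consumes most of the identification.  It is the pipeline
  default.
* `intercept=True`: a free intercept, the form canonical LD-score
  regression uses to absorb confounding; available everywhere.

**Selection index.**  For k traits (focal first) the weights solve
`V w = C` with

    V_kk = h²_k/M + 1/N_k      V_kl = r_g(k,l)·h_k·h_l/M      C_k = r_g(f,k)·h_f·h_k/M

solved by a dense linear solve with a condition-number guard (error above
1e12, naming the most strongly coupled trait pair).  The adjusted effect of
marker i is `w′β̂_i`, and both scores are plain dot products of allele counts
with effects: `ST = Σ X_i β̂_i`, `MT = Σ X_i (w′β̂)_i`.  Estimated r_g enters
V clamped to ±0.999, and the matrix is eigenvalue-clipped (floor 1e-3) to
the nearest correlation matrix when estimation noise leaves it indefinite.
Non-positive h² estimates are floored at 1e-6 before weighting, with a
warning; the raw estimate is retained for reporting.

**M, the effective number of independent segments.**  `M = 60,000` is the
default, appropriate to a genotyped human cohort of unrelated Europeans
(~600k markers whose mean LD score is ~10).  The self-consistent general
rule, used by the pipeline when `M` is not given, is `M = m / mean(l)`: the
LDSC slope measures per-marker signal variance `h²·l/m`, so the marginal
effects being weighted have average signal variance `h²/(m/mean(l))` — the
deflated marker count is exactly the "independent segments" the index
formula wants, and 599,297/10 ≈ 60,000 recovers the human default.

**Marker selection.**  LD pruning is greedy with P-value priority: visit
markers in ascending focal-trait P (ties broken by genomic position), keep
a marker iff its r~2 with every already-kept marker within the window is
below the ceiling.  The kept set is therefore exhaustively verifiable, and
the same subset (chosen once, from the focal statistics) is reused for all
k traits.  P-value thresholding is strict (`p < p_max`).  The default grids
are r² < {0.1, 0.5, 0.9} and P < {0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5,
0.7, 0.9, 0.99} for single-trait scoring, P < {0.001, 0.01, 0.05, 0.1, 0.2,
0.5, 0.75, 0.99} for multi-trait scoring; both grids are configuration
lists.  Missing genotypes are imputed to 2·af of the training frequency at
scoring time.

**Evaluation.**  The incremental Nagelkerke pseudo-R² compares nested
logistic models (covariates vs covariates + score):
`R² = (1 − e^(−LR/n))/(1 − e^(2L₀/n))`.  Percentile stratification assigns
equal-occupancy rank bins (ties by stable sample order, seed-independent),
reports per-bin prevalence, and fits each bin against the reference bin
(50th percentile) separately with covariates — separate fits degrade
gracefully when a bin has no cases, which a joint 100-indicator model does
not.  Fold SEMs use the k−1 denominator.

## Synthetic cohorts

Genotypes: two independent latent Gaussian haplotype streams follow an
AR(1) process within blocks of `block_size` markers (restarted at block
boundaries) and are thresholded at the Hardy-Weinberg quantile of each
marker's MAF (drawn uniformly from `maf_range`), then summed — exact HWE
marginals, tunable within-block r² decay, zero across-block LD in
expectation.  The AR parameter may be a per-block range (default
(0.2, 0.95)): heterogeneous LD strength along the genome is both the
realistic regime and the one in which LD-score regression is
well-identified — with a common block correlation the LD scores are nearly
constant and the slope is barely estimable.

Phenotypes: true effects at `n_causal` uniformly chosen markers are drawn
jointly across traits with covariance `r_g·h_k·h_l/n_causal` on
standardized genotypes; independent residuals bring each trait to unit
genetic-plus-residual variance; standardized sex and age effects
(default 0.1 each) shift the liability; binary traits threshold the
liability at the normal quantile of 1−K (using the theoretical liability
SD including covariate variance, so the realized case fraction is binomial
around K).  All randomness flows from one seed via named SeedSequence child
streams (genotypes, missingness, effects, residuals, covariates, causal),
so stages are independently reproducible.

What the generator does **not** emulate: realistic human LD maps and
recombination structure, population stratification or relatedness (the PC
covariate columns are constant-zero placeholders), imputation dosages,
MAF-dependent genetic architecture, strand ambiguity.  Passing tests
demonstrate the estimators' internal consistency under the additive
liability model, not robustness to those real-data complications.

## Reference studies (problem sizes)

* **Parameter recovery** (`experiments.recovery_simulation`): two
  quantitative traits, h² = 0.5 each, r_g = 0.6, n = 2,000, m = 5,000,
  fully polygenic (every marker causal — the infinitesimal architecture
  the summary-statistic regressions assume), LD-score window ±100 markers
  (blocks are 20, and truncation only drops zero-mean noise terms).
  Across 20 seeds the mean recovered h² is within ±0.05, r_g within ±0.1,
  n_eff within ±10%.
* **Single- vs multi-trait comparison** (`experiments.mt_vs_st_experiment`):
  a cohort of n = 8,000 with m = 2,000 markers and eight traits — a binary
  focal disease at prevalence 0.056 with liability h² = 0.30, and seven
  quantitative information traits (h² 0.15–0.50) whose genetic
  correlations to the disease span 0.30–0.58, echoing a diabetes-like
  trait set (bmi and medication use the strongest).  Train on two thirds,
  score the held-out third, take the best incremental R² over
  P < {0.01, 0.1, 0.5, 0.99} at r² < 0.9.  The cohort size is chosen so
  the held-out fold holds ~150 cases; with fewer the evaluation noise
  exceeds the MT−ST margin.  Across 10 seeds the multi-trait score wins in
  ≥ 8 and improves the mean R² by roughly a third — the qualitative
  analogue of the improvements reported for biobank-scale data.

## Numerical choices and edge cases

* IRLS tolerance 1e-8 on deviance, max 50 iterations; non-convergence →
  marker invalid.  Linear SEs use the t distribution with per-marker
  residual dof.
* Inverse-rank normalization uses the Blom offset
  `Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks for ties; constant input
  is an error.
* OR conversion: `β = ln(OR)`, `se = |β|/Φ⁻¹(1 − p/2)`; OR = 1 or p = 1
  leave the marker flagged invalid (0/0 and division by zero).
* Harmonization matches by marker id with a chrom:pos cross-check; swapped
  alleles negate β and complement af; pairs matching neither orientation
  are dropped and counted.  A/T and C/G strand ambiguity is **not**
  specially handled — documented limitation.
* Percentile bins of tied scores follow stable sample order; the reference
  bin's odds ratio is exactly 1 by construction.
* PLINK1 codec: SNP-major, codes 00/01/10/11 = hom-A1/missing/het/hom-A2,
  A1 is the counted effect allele, bim positions 1-based; exclusion regions
  are 1-based inclusive.

## Known limitations

Marginal effects only (no LDpred-style joint effect estimation, by design);
no mixed-model association; no partitioned LD-score regression or
sample-overlap intercept estimation; no X-chromosome handling; no AUROC or
calibration metrics.  The percentile odds-ratio model fits each bin against
the reference separately rather than one joint model with 99 indicators.
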
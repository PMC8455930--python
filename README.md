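# mtgrs — multi-trait genomic risk scores

Genome-wide risk scores (GRS) for a disease are usually built from that
disease's own GWAS alone.  When the disease is genetically correlated with
easily measured traits — body-mass index, blood pressure, medication use —
those traits' far better-powered marker-effect estimates carry usable
signal.  `mtgrs` implements the full multi-trait workflow for researchers
working with biobank-style cohorts and public GWAS summary statistics:

1. **Marginal GWAS** — per-marker linear/logistic regression with
   covariates, batched across markers; QC filtering (MAF, missingness,
   exclusion regions); inverse-rank normalization of quantitative traits;
   harmonization of external summary statistics to the cohort's allele
   orientation, including OR → β conversion.
2. **Genetic parameters from summary statistics** — bias-adjusted LD
   (`r~² = r² − (1−r²)/(N−2)`), windowed LD scores
   (`l_i = Σ_k r~²(i,k)`, 5,000-marker window), and LD-score regression
   for heritability and genetic correlation:

       ĥ² slope of (β̂/se)² on n_eff·l/m        r̂_g slope of z₁z₂ on √(n₁n₂)·l/m, ÷ √(ĥ₁²ĥ₂²)

   with `n_eff = median 1/(2·af(1−af)·se²)` and an observed→liability
   scale transform for binary traits.
3. **Selection-index weighting** — optimal trait weights `w = V⁻¹C` with
   `var(β̂_k) = h²_k/M + 1/N_k` and `cov(β̂_k, β̂_l) = r_g h_k h_l/M`
   (M = 60,000 effective segments for a genotyped human cohort); adjusted
   marker effects `w′β̂_i`; four weighting scenarios (S1–S4) combining
   internal, information-trait and external focal statistics.
4. **Scoring and evaluation** — clumping (greedy LD pruning with P-value
   priority) + P-value thresholding; `ST-GRS = Σ X_i β̂_i` and
   `MT-GRS = Σ X_i (w′β̂)_i`; incremental Nagelkerke
   `R² = (1−e^(−LR/n))/(1−e^(2L₀/n))` over a covariate-only model;
   percentile risk stratification with odds ratios against the 50th
   percentile; 10-fold cross-validated orchestration.
5. **Synthetic cohorts** — LD-blocked genotypes (latent AR(1) haplotype
   copula) and k correlated traits under an additive liability model, so
   the whole pipeline is testable without access-restricted data.

Formats: PLINK1 bed/bim/fam (codec included), TSV phenotypes and summary
statistics (with a header alias map), YAML configuration.

## Worked example

Simulate a disease cohort (prevalence 5.6%, liability h² = 0.30, seven
correlated information traits), run the single- vs multi-trait comparison,
and inspect the weights:

```python
import numpy as np
from mtgrs.experiments import mt_vs_st_experiment

res = mt_vs_st_experiment(seed=0)
print(f"ST R2 {res['r2_st']:.4f}  MT R2 {res['r2_mt']:.4f}")
for lab, w in zip(res["trait_labels"], np.round(res["weights"], 3)):
    print(f"  {lab:<11} {w:+.3f}")
```

prints

```
ST R2 0.0321  MT R2 0.0596
  disease     +0.091
  height      +0.157
  bmi         +0.314
  pulse       +0.374
  dbp         +0.102
  sbp         +0.026
  smoking     +0.631
  medication  +0.315
```

The single-trait score explains 3.2% of the disease risk on the Nagelkerke
scale; re-weighting the same markers with the selection index nearly
doubles that.  Per-seed weights are noisy (smoking happens to top this
seed), but averaged over seeds the largest information-trait weights go to
the traits with the strongest genetic correlation to the disease — bmi and
medication use — and across ten seeds the multi-trait score wins every
time (mean R² 0.070 vs 0.055, a ~27% improvement).

The same workflow is scriptable from the shell:

```bash
mtgrs simulate --config sim.yaml --out cohort
mtgrs qc       --bfile cohort --out cohort_qc
mtgrs gwas     --bfile cohort_qc --pheno cohort.pheno.tsv --trait disease \
               --model logistic --out disease.tsv
mtgrs ldscore  --bfile cohort_qc --window 5000 --out ld.tsv
mtgrs ldsc     --sumstats disease.tsv --ldscores ld.tsv --m 2000 --out params.yaml
mtgrs run      --config pipeline.yaml   # full cross-validated grid
```

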
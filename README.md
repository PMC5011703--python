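# twinsem

Maximum-likelihood ACE structural equation models for MZ/DZ twin cohorts:
heritability, genetic correlations, independent-pathway factor models,
correlation clustering, pair-preserving permutation tests and a synthetic
twin-cohort generator.

## The problem

The classical twin design compares monozygotic (MZ) pairs, who share all
segregating genes, with dizygotic (DZ) pairs, who share half on average.
For a phenotype vector **y** measured on both members of a pair, the
phenotypic covariance decomposes into additive genetic (A), shared
environmental (C) and unique environmental (E) components.  A twin pair's
2p-variate covariance is

    Σ_pair = [[ A + C + E ,  γ_A·A + C ],
              [ γ_A·A + C ,  A + C + E ]]

with γ_A = 1 for MZ and 0.5 for DZ pairs (the shared environment is fully
correlated in both groups — the equal-environments assumption).  Fitting
this model by maximum likelihood yields the heritability
h² = σ²_A / (σ²_A + σ²_C + σ²_E), and its multivariate extensions yield
genetic correlations r_G(i,j) = A_ij / √(A_ii·A_jj) between traits.

The package targets volumetric brain phenotypes from twin neuroimaging
studies — regional grey-matter volumes with age, sex, scanner and
intracranial volume (ICV) adjusted in the model means — but nothing in it
is specific to imaging.

## What it provides

- **`fit_ml` / `fit_model_ladder`** — univariate ACE/AE/CE/E maximum
  likelihood with covariates in the means, profile-likelihood 95%
  intervals (`profile_ci`), likelihood-ratio tests (`lrt`), AIC, and
  ML intraclass correlations (`icc`).
- **`fit_cholesky`** — saturated multivariate (triangular-decomposition)
  ACE models; `component_correlations` extracts genetic, shared- and
  unique-environment and phenotypic correlation matrices; `test_rg_zero`
  tests r_G = 0.
- **`fit_bilateral_ipm` / `test_bilateral_symmetry`** — the left/right
  independent-pathway model with tied common loadings, testing r_G = 1
  (no hemisphere-specific genetic variance), r_G = 0 and left/right path
  equality.
- **`fit_kfactor_ipm` / `variance_proportions`** — k common genetic and
  unique-environment factors plus one shared-environment factor over p
  regions, with each factor's share of total genetic variance.
- **`eigen_scree`, `cluster_correlations`, `select_k`** — factor-count
  screening and complete-linkage clustering of correlation matrices on
  the distance 1 − r, with silhouette-based cluster-count selection.
- **`perm_test`** — zygosity-group comparisons whose permutation null
  moves twin pairs as units.
- **`simulate_cohort` / `simulate_from_fit`** — synthetic MZ/DZ cohorts
  from any ACE structure, with realistic covariate laws (multi-site
  scanner assignment shared within pairs, opposite-sex DZ pairs).
- **`run_pipeline`** — the end-to-end analysis over a phenotype table,
  plus a thin `twinsem` CLI (`simulate`, `fit-univariate`,
  `fit-cholesky`, `fit-ipm`, `cluster`, `permtest`, `run-all`).

## Worked example

`examples/01_univariate_heritability.py` simulates 93 MZ and 68 DZ pairs
with generating variance shares (a², c², e²) = (0.6, 0.1, 0.3) and fits
the model ladder:

```
cohort: 322 individuals, design columns: ['intercept', 'age', 'sex', 'scanner[2]', 'scanner[3]', 'scanner[4]', 'icv']
h2 = 0.565  95% CI (0.234, 0.783)
c2 = 0.170  e2 = 0.265
implied twin correlations: r_MZ = 0.735, r_DZ = 0.452

model   loglik      AIC     LRT vs ACE (stat, df, p)
ACE     -413.81    847.62
AE      -414.28    846.56     0.94  1  0.332
CE      -419.32    856.64    11.02  1  0.001
E       -452.21    920.41    76.79  2  0.000
```

h² is the estimated share of phenotypic variance attributable to additive
genetics; the CE and E rows show that removing the genetic component
significantly worsens the fit, while the AE model is competitive by AIC
(the shared-environment share is small).  The remaining examples cover
genetic correlations, bilateral symmetry testing, factor discovery with
clustering, the published 11-region correlation matrix, and permutation
demographics.

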
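# Methods

## The twin model

Each twin pair contributes a 2p-variate normal observation: the stacked
phenotype vectors of twin 1 and twin 2.  The mean of twin *j* is
M + B·x_j, where x_j holds the covariates (intercept, age, sex coded
1 = male / 0 = female, scanner dummies — four levels coded with three
indicators against a configurable reference — and ICV, in that order).
The covariance is assembled from the A, C and E component matrices with
cross-twin weights γ_A = 1 (MZ) or 0.5 (DZ) and γ_C = 1 for both
zygosities.  The equal-environments assumption (γ_C = 1) is fixed, not
configurable.  Covariates act only on the means; phenotypes are never
pre-residualised.

All components are parameterised through path coefficients — loading
matrices whose outer products form A, C and E — so the components are
positive semidefinite by construction and the optimisation is
unconstrained.  Reported paths are sign-fixed (nonnegative diagonals for
triangular loadings; first nonzero loading per factor positive),
removing reflection indeterminacy without changing the implied
covariances.

Three parameterisations are available:

- **Univariate / Cholesky**: free lower triangles per included
  component.  ACE/AE/CE/E submodels drop whole components.  Individual
  loading entries can be pinned to zero, which is how the r_G = 0 test
  constrains the genetic cross-path of a bivariate model.
- **Bilateral independent-pathway**: one common factor per component
  with loadings tied equal across the two hemispheres (the
  identification constraint), plus hemisphere-specific paths.  The
  r_G = 1 test removes both specific genetic paths (2 df); the r_G = 0
  test removes the common genetic factor (1 df); the lateral-symmetry
  equality test ties left and right specific paths per component.
- **k-factor independent-pathway**: k common genetic and
  unique-environment factors with echelon zeros (Λ[i, j] = 0 for j > i)
  pinning the factor rotation, one common shared-environment factor by
  default (region-specific C paths behind a flag), and region-specific
  genetic and unique-environment paths.  The factor-rotation rule
  matters because the variance-proportion summary (below) is
  rotation-dependent; any fixed identification makes it reproducible,
  and the echelon rule is the conventional one.

## Likelihood and optimisation

For a fixed covariance structure the mean coefficients B have a
closed-form generalised-least-squares optimum, so the likelihood is
concentrated over B and the optimiser runs only over covariance paths.
All per-pair sums reduce to per-zygosity cross-moment matrices, making a
likelihood evaluation independent of the number of pairs; this is what
keeps the replicate simulations (hundreds of full ML fits) cheap.

Phenotypes are standardised internally to unit pooled variance before
optimisation and the fitted paths are mapped back to raw units
afterwards.  This makes the numerics scale-free — a trait measured in
mm³ or cm³ yields identical correlations — at one interpretive cost:
equality constraints (the bilateral loading ties) apply to standardised
path coefficients.  For left/right volumes, whose scales are nearly
identical, the distinction is immaterial.

Optimisation is quasi-Newton (L-BFGS-B, numerical gradients, ftol
1e-11) from a moment-based start — A, C, E estimated from OLS-residual
twin covariances via Â = 2(Γ_MZ − Γ_DZ), Ĉ = 2Γ_DZ − Γ_MZ,
Ê = Σ̂ − Γ_MZ, projected to the PSD cone — plus seeded perturbations of
it (5 starts by default; large models default to fewer because the
moment start is already close).  Non-positive-definite proposals return
−∞ and the optimiser backs away.  The convergence flag is honest: it
reports whether any start converged, and likelihood-ratio tests raise an
error if a nested optimum exceeds its full model's beyond 1e-4.

Pairs with missing phenotype values are dropped by default
(complete-pair analysis); `include_incomplete=True` switches to a
full-information likelihood that evaluates each incomplete pair's
density over its observed entries.

## Inference

**Profile intervals.**  95% intervals for h², c², e² invert the
likelihood-ratio criterion 2(ℓ_max − ℓ_profile(t)) = 3.841 (χ²₁ at
0.95) on the proportion scale: at each fixed share t the remaining two
shares and the total variance are re-optimised (bounded L-BFGS-B on the
mixing weight, warm-started along the profile), and the bound is found
by Brent's method to 2e-4.  Estimates on the boundary yield one-sided
intervals pinned at 0 or 1.  Simulation at the default study size puts
empirical coverage near nominal (the acceptance suite checks 91–99% at
400 replicates).

**Likelihood-ratio tests** use the plain χ² reference with df equal to
the parameter-count drop, even when a variance component sits on its
boundary — no 50:50 mixture correction.  This matches common practice
in twin SEM and is conservative at the boundary; the E-vs-ACE test, for
example, rejects less often than its nominal level.

**ICC.**  Within-pair intraclass correlations come from an ML bivariate
normal with common covariate-adjusted mean and variance for both twins
and free correlation r, with a profile-likelihood interval — not the
ANOVA estimator.  A double-entry Pearson correlation serves as the
cross-check in the tests.

**Permutation demographics.**  t (continuous) and chi-square
(categorical) statistics are computed on individuals, but their null
distribution permutes zygosity labels over whole pairs, keeping the
MZ/DZ pair counts fixed — twins are never split.  p-values carry the
add-one correction (B + 1 in the denominator), so they cannot be zero;
B defaults to 10000.

## Structure discovery

Clustering operates on d(i, j) = 1 − r(i, j) (an option allows
1 − |r|): a negative genetic correlation maps to a distance above one,
preserving sign-sensitive grouping.  Complete linkage is the default —
on the published 11-region genetic matrix it reproduces the
three-group solution, whereas average linkage is sensitive to the
weakly-attached nucleus accumbens.  Items are sorted lexicographically
before linkage so the tree is invariant to input order.

The cluster count maximises mean silhouette width over cuts k = 2…6,
**excluding cuts that produce singleton clusters** (falling back to all
cuts when none qualify).  A one-member cluster has no within-cluster
dissimilarity and receives silhouette 0 by convention; including such
cuts rewards peeling single weakly-correlated items off and, on the
published matrix, would prefer isolating the nucleus accumbens over the
three-group solution.  The eigenvalue screen reports both the elbow
count (eigenvalues preceding the largest consecutive drop) and the
strict Kaiser count (λ > 1).

## The synthetic cohort generator

The generator inverts the model: per pair it draws genetic deviates
with cross-twin correlation γ_A (MZ twins share one draw; DZ twins get
u₀ + uᵢ with u ~ N(0, A/2)), one shared environmental deviate, and
independent unique-environment deviates, then adds M + B·x.  Defaults
emulate an older-adult multi-site cohort: 93 MZ + 68 DZ pairs (322
individuals), age uniform on 65–85 years shared within pair, sex
Bernoulli with P(female) = 0.668 (shared for MZ, independent per twin
for DZ — opposite-sex DZ pairs arise naturally), four scanners with
probabilities (80, 36, 114, 92)/322 shared within pair, and ICV drawn
as an independent N(1.45×10⁶, (1.5×10⁵)²) mm³ covariate.  ICV is
simulated as a covariate rather than a phenotype because the analyses
condition on it in the means, even though head size is itself
heritable; generating it as a phenotype is possible by including it in
the structure instead.

What the generator does **not** emulate: non-normal phenotypes,
skewness or outliers from segmentation error, sex-limitation effects in
A, chorionicity, scanner-specific variance differences (scanners shift
means only), missing data, or exclusion/QC processes.  Passing tests
therefore certify the estimators under the model's own assumptions, not
robustness to their violation.

## Numerical choices and degenerate inputs

- Zero or near-zero component variances: correlations whose
  denominator variance is below 1e-10 of the trait's total variance are
  flagged *undefined* rather than reported as ±1 or propagated as NaN;
  clustering refuses matrices with undefined entries and names the
  offending pairs.
- PSD projections (moment starts, generator square roots) use
  eigenvalue clipping with floors proportional to the matrix trace.
- The AIC identity aic = −2ℓ + 2k (k counts covariance paths plus mean
  coefficients) holds for every fit and is asserted in the tests.
- Ties in clustering are broken deterministically by label order; the
  k-cluster partition always refines the (k−1)-cluster one.
- Seeds: every stochastic routine takes an explicit seed; the same seed
  reproduces bit-identical cohorts and pipeline outputs.

## Simulation scale

Replicate counts follow the package's validation design: 200 cohorts
per recovery setting, 200 replicates for the bilateral-symmetry
retention rate, 400 for profile-interval coverage, and 300 datasets for
permutation calibration; recovery of k-factor loadings is demonstrated
at 2500 pairs, where sampling noise no longer masks the factor pattern.

## Known limitations

- **Boundary bias of ĥ² at small c².**  With a generating
  shared-environment share near zero, the nonnegativity of ĉ² censors
  sampling noise at the boundary, and the excess mass E[ĉ²] > c² comes
  out of ĥ²: at 93 + 68 pairs the mean ML heritability estimate runs
  roughly 0.06–0.07 below a generating value of 0.78 (the package's own
  recovery simulations compute this).  The effect shrinks with sample
  size, vanishes for interior c² (the amygdala-like setting recovers
  within 0.02), and disappears under the AE submodel.  This is a
  property of boundary-constrained ML itself, not of the
  implementation, which is verified against an independent density
  oracle and a global optimiser.
- LRT p-values at variance boundaries are conservative (see above).
- The k-factor model's variance proportions depend on the echelon
  identification; a different rotation rule would redistribute shares
  between factors with identical fit.
- Profile intervals assume the χ²₁ calibration of the likelihood
  ratio, which is approximate at these sample sizes near boundaries.
- The ICC model assumes exchangeable twins within a pair (common mean
  and variance), which is standard for same-cohort volumetric data.
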
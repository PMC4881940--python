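# Methods

## Model

Pairs are the sampling unit. For one outcome composite measured at the
four occasions, each twin's scores are stacked into an 8-vector (twin 1
stages 1–4, then twin 2). The ACE Cholesky model parameterizes the pair
covariance through three lower-triangular 4×4 loading matrices Λa, Λc, Λe
(columns = factors, rows = stages):

* within-twin covariance ΛaΛaᵀ + ΛcΛcᵀ + ΛeΛeᵀ,
* cross-twin covariance r·ΛaΛaᵀ + ΛcΛcᵀ with kinship r = 1 (MZ) or
  0.5 (DZ), and no cross-twin E covariance.

This encodes the standard twin assumptions: additive gene action, equal
shared environments for MZ and DZ pairs, random mating, no gene-environment
interaction or correlation, and E absorbing measurement error. Squared
loadings divided by the stage's total variance are the standardized
contributions; factor *j*'s diagonal entry at stage *j* is the innovation
arising at that stage, and the *stage-specific proportion* is that
innovation divided by the component's summed contributions at the stage.

Estimation is two-group Gaussian maximum likelihood. Pairs are grouped by
missingness pattern and collapsed to per-pattern sufficient statistics
(count, mean, ML scatter), so one likelihood evaluation costs
O(patterns × 8³) regardless of cohort size. Stage means (shared between
twins and zygosity groups) are profiled out in closed form at every
evaluation. The default missing-data mode is full-information ML on each
pair's observed sub-vector; a complete-pairs mode exists as a cross-check
and yields the identical likelihood function on fully observed data.

### Numerical choices

* Optimization is over loadings, not variances, so every implied component
  matrix is positive semi-definite without constraints; only the Λe
  diagonal is bounded below (1e-6) to keep the pair covariance positive
  definite. Column signs are indeterminate and canonicalized to nonnegative
  diagonals after fitting.
* Starting values come from a method-of-moments decomposition of the
  empirical within/cross blocks (Cov_A = 2(B_MZ − B_DZ), Cov_C = 2B_DZ −
  B_MZ, Cov_E = W − B_MZ, eigenvalue-clipped to PSD and Cholesky-factored);
  L-BFGS-B with five seeded jittered restarts (default) guards against
  local optima, with convergence tolerance 1e-8 on the objective.
* Degenerate covariances encountered during optimization (singular Σ) are
  scored as −∞ likelihood rather than raised.
* Confidence intervals are profile-likelihood intervals: the bound is where
  the profiled deviance crosses the χ²₁ critical value, located by
  bisection with an SLSQP equality-constrained inner fit (quadratic-penalty
  Nelder-Mead fallback). Standardized quantities are profiled inside
  [0, 1]; at the zero boundary the profile is computed exactly by fixing
  the loadings that feed the quantity at zero, so boundary estimates report
  .00 endpoints. Which construction the original Mx analyses used is not
  stated anywhere we could verify; profile likelihood is implemented and
  labeled as such.

### Simpler estimators

Intraclass correlations use the one-way random-effects ANOVA estimator
(MSB − MSW)/(MSB + MSW) per zygosity group, with the one-sided F test for
the p-value; a double-entry Pearson correlation is available as an
alternative view but the ANOVA ICC is what the model suite consumes.
Falconer moment estimates are a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ,
e² = 1 − rMZ; the identity a² + c² + e² = 1 is exact, out-of-range values
are flagged rather than silently clamped, and an explicit truncated
variant clamps and renormalizes.

## Growth model

Mean intervention response is modeled by full-ML multilevel growth curves
with occasions (time = 0..3) nested in individuals nested in pairs:
fixed effects γ00 + γ10·time (+ γ20·time2, time2 = 0,0,1,2, in the
piecewise model), a pair-level random intercept, correlated
individual-level random intercept and slope(s), and iid residuals. The
unconditional model constrains γ20 = 0 and drops the time2 random slope.
The marginal likelihood of each pair's observation vector is maximized
over the variance parameters (Cholesky-parameterized random-effect
covariance) with fixed effects profiled by GLS; pairs sharing an
observation pattern are collapsed to sufficient statistics. Fixed-effect
standard errors come from the GLS information matrix; t statistics use
residual df = n_observations − n_fixed_effects; variance parameters are
tested only by likelihood ratio. AIC/BIC count all free parameters
(fixed + variance). Time is coded in occasion units, not weeks, matching
the per-period scale of the intervention-slope estimates; week coding is a
one-line change in the time-code table. Whether the two slopes should also
vary at pair level is genuinely open; they vary only at individual level
here.

Growth models consume the baseline-standardized composites, not the
twin-analysis table: the rank-normal and covariate corrections are applied
per stage and therefore centre every occasion, which would remove the mean
trajectory those models exist to estimate.

## Preprocessing

Order is fixed: (1) scale scores = mean of items after reverse-keying,
requiring ≥ 50% of items present; (2) standardize each scale on its
baseline mean/SD and average into the two composites (well-being =
happiness + life satisfaction; mental health = negated depression +
negated anxiety, the sign flip commuting with standardization), computed
only where both constituent scales are present; (3) van der Waerden
transform Φ⁻¹(r/(n+1)) with average ranks for ties (the transform's tie
rule is unstated in the source analyses; average ranks is the conventional
choice), applied per outcome and stage by default (per-stage vs pooled is
config-exposed); (4) OLS residualization on age and sex pooled across all
individuals, re-standardized to mean 0, SD 1.

## Synthetic cohorts

The generator draws one 8-vector per pair from the exact joint normal
(Cholesky factor of the implied pair covariance) rather than summing
component draws — exact second moments, no approximation beyond sampling
noise. Defaults are the study conditions: 167 MZ + 208 DZ same-sex pairs
(750 individuals), pair-shared ages N(16.55, 0.51²) truncated to [14, 19],
58% female, occasions at weeks 1/4/7/10, flat control phase and +0.07 SD
per occasion from the intervention on, and generating loadings equal to
the element-wise square roots of the published standardized component
tables (all signs positive — only squared contributions are reported, so
the sign structure is a modeling choice). Attrition is emulated as MCAR at
the individual-stage level with per-stage retention ≈ .995/.985/.97/.99;
no attrition mechanism is claimed.

Item-level data use a graded-threshold stand-in: item latent =
loading·score + noise, thresholded at equally spaced cut points spanning
±2.5 latent SD, reverse-keyed items emitted flipped. The measurement model
of the real instruments is unknown; this scaffolding supports testing the
scoring path and is not claimed to reproduce published internal-consistency
coefficients.

What the simulator does **not** emulate: activity compliance and the
related exclusion rules, opposite-sex pairs, non-normal latent traits,
informative attrition, and any gene-environment interplay excluded by the
ACE assumptions. Passing recovery tests therefore demonstrates correctness
of the estimators under the model's own assumptions, not robustness of the
substantive findings to their violation.

## Power

`power_heritability` simulates standardized univariate pair scores (MZ
correlation a² + c², DZ correlation a²/2 + c²), fits ACE and CE by ML, and
refers the LRT to the 50:50 mixture of χ²₀ and χ²₁ appropriate for a
variance component on its boundary (level-α critical value = χ²₁ quantile
at 1 − 2α; 2.706 at α = .05). Power fits use the method-of-moments start
without restarts — the three-parameter likelihood is smooth and the null
calibration checks would expose optimization failures. The assumed c² of
the original design calculation is unknown; c² = 0 is the documented
default here.

A relevant finding from this package's own calculations: at the study size
with c² = 0, both the Monte-Carlo estimate and an independent analytic
noncentrality calculation put the power to detect a² = 0.40 at ≈ 71–72%,
not 80%. The mechanism is that with no shared environment the CE null can
absorb much of the pair covariance into C, flattening the likelihood
contrast. The 80% figure is consistent with the same test when a modest
shared-environment variance (c² ≈ 0.1, matching the baseline Falconer c²
of the well-being composite) sharpens the MZ/DZ contrast. The acceptance
run reports the honestly computed c² = 0 value.

## Problem sizes

Recovery checks run at the sizes where their tolerances are meaningful:
100,000 pairs/group for univariate recovery (±0.02), 50,000 pairs/group
for the Cholesky fit (±0.02 on the intervention-stage E innovation), 2,000
replicates for the power estimate (MC SE ≈ 0.01), 40–60 seeded replicates
at the 375-pair design size for growth fixed-effect calibration, and ≤ 5
pairs for the brute-force likelihood oracles (agreement to 1e-8). These
sizes are the package's own choices balancing Monte-Carlo error against
runtime.

## Known limitations

No ADE or sex-limitation models; no cross-trait (bivariate) model linking
the two composites; single-outcome Cholesky only. Profile CIs for all 42
table cells are computed only when requested (`models.compute_ci`), as
they dominate runtime at desk scale. The ICC p-values assume normality;
the preprocessing pipeline makes that defensible but small-sample boundary
behavior (negative ICCs) is reported as computed.
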
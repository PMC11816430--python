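# Methods

This note documents the statistical machinery in `lpfsbench`: the models,
the estimation and numerical choices, what the synthetic-data generator
does and does not emulate, and the known limitations.

## The measurement model

The LPFS-BF 2.0 yields an n × 12 matrix of ordered categorical responses
with codes 1–4.  Category codes stay 1-based everywhere a user sees them
(totals span 12–48); the estimation routines convert to 0-based indices at
a single boundary (`ResponseMatrix.zero_based`).

**Graded response model (GRM).** For item i with discrimination aᵢ > 0 and
ordered difficulties bᵢ₁ < bᵢ₂ < bᵢ₃, the cumulative response curves are

    P(Xᵢ ≥ k + 1 | θ) = logistic(aᵢ (θ − bᵢₖ)),   k = 1..3,

and category probabilities are successive differences.  The logistic
metric is used without the D = 1.702 normal-ogive scaling: the shipped
calibration's slopes (1.77–3.08) are on this metric, and the package's
category-probability spot checks only reproduce published values under
this convention.

**Generalized partial credit model (GPCM).** Category logits are
cumulative sums of aᵢ(θ − dᵢⱼ); probabilities are the softmax.  Step
parameters need not be ordered.  The GPCM is fitted as the competing
specification for the Vuong comparison; benchmarks always come from the
GRM fit (mirroring the analysis the package reproduces, where the GRM was
preferred), with a logged warning if the Vuong test ever disagrees.

## Estimation

Bock–Aitkin EM (marginal maximum likelihood):

* **Latent grid.** 61 equally spaced nodes on [−6, 6] with standard-normal
  density weights renormalized to sum to one.  Gauss–Hermite nodes are
  available (`LatentGrid.gauss_hermite`).  Doubling the node count changes
  a fitted log-likelihood by well under 1e-3 (tested).
* **Scale identification.** The N(0, 1) prior is fixed, so θ is identified
  with mean 0 and SD 1; "latent mean + m SD" is simply θ = m.
* **Internal parametrization.** Items are estimated in slope–intercept
  form (cₖ = −a bₖ); for the GRM, intercept ordering is enforced through a
  log-decrement parametrization (c₁ free, subsequent intercepts obtained
  by subtracting exponentials), so the ordering constraint can never be
  violated during optimization.  Parameters are converted back to (a, b)
  at the boundary.
* **E-step.** Posterior node weights per respondent from the current
  parameter tables; expected category counts per item and node.
* **M-step.** Per-item L-BFGS-B on the expected complete-data negative
  log-likelihood (at most 50 inner iterations).  The update is kept only
  if it improves the M-step objective, which makes the procedure a
  generalized EM and guarantees a monotone marginal log-likelihood; the
  per-cycle trace is stored and asserted non-decreasing in the tests.
* **Start values.** Slopes 1.0; difficulties at inverse-normal marginal
  cumulative proportions.
* **Convergence.** Maximum absolute internal-parameter change < 1e-4, or
  500 cycles (non-convergence is flagged on the result, not raised).
* **Degenerate items.** An item with a single observed category is
  rejected; unobserved categories are collapsed to contiguous codes with a
  warning, and the item is fitted with the reduced category count.
* **Scoring.** EAP θ estimates and posterior SDs on the same grid.

**Vuong comparison.** Per-respondent marginal log-likelihood differences
dᵢ = llᴬᵢ − llᴮᵢ give ω² = Var(dᵢ) (distinguishability) and the
directional statistic z = √n · mean(d)/sd(d); positive z favours model A.
The distinguishability p-value uses a delta-method normal approximation
for the sampling variance of ω² — an approximation to the
eigenvalue-weighted chi-square of the exact two-step test, adequate for
the clear-cut comparisons exercised here.  Identical per-case likelihoods
are reported as indistinguishable with z = 0.  No AIC/BIC correction is
applied even though the models' parameter counts differ; this matches the
plain two-step statistic the package reproduces and is a documented
limitation.

## Dimensionality screen

* **Polychoric correlations.** Two-step ML: thresholds from marginal
  inverse-normal cumulative proportions, then ρ maximized over
  (−0.999, 0.999) by bounded Brent search (xatol 1e-6) of the
  bivariate-normal cell likelihood.  Rectangle probabilities are computed
  by a vectorized one-dimensional reduction: an outer 48-point
  Gauss–Legendre panel per x-strip with the inner y-integral evaluated as
  a difference of univariate normal CDFs.  This is accurate to ~1e-8 at
  moderate |ρ| and keeps parallel analysis (hundreds of simulated
  matrices) inside seconds; the tests cross-check it against a grid-search
  oracle built on scipy's bivariate normal CDF.
* **Smoothing.** Near-singular matrices are eigenvalue-floored at 1e-6 and
  rescaled to unit diagonal, with a logged warning, before PCA/factoring.
* **Parallel analysis.** Reference eigenvalues are the mean (Horn's
  classical choice; 95th percentile switchable) over ≥100 datasets built
  by permuting each observed column independently — preserving marginals
  while destroying dependence.  The retained count is the number of
  leading observed eigenvalues exceeding their reference.  For pure-noise
  input the first observed eigenvalue is statistically exchangeable with
  its reference, so the retained count at a specific seed is what the
  deterministic test asserts.
* **Velicer's MAP.** For k = 0..m−2 principal components partialled out,
  the mean squared off-diagonal partial correlation is recorded; the
  suggested count is the argmin.
* **One-factor minres.** Loadings minimize the sum of squared off-diagonal
  residuals of R − λλᵀ, with analytic gradient, SMC-based start values,
  and a vanishing (1e-9) ridge that selects the null solution when the
  criterion is degenerate (identity input).  Boundary loadings are capped
  and flagged as Heywood cases.  Note that minres-on-polychoric loadings
  from simulated unidimensional data are systematically higher than the
  shipped calibration's loadings (which derive from a categorical-data
  CFA on real responses); the shipped loadings are therefore treated as
  inputs to ω, not as recovery targets.
* **Reliability.** ω = (Σλ)² / ((Σλ)² + Σ(1 − λ²)) from standardized
  loadings; the shipped loadings give ω = 0.92.

## Benchmarks and classification

The test characteristic curve T(θ) = Σᵢ E[Xᵢ | θ] with
E[Xᵢ | θ] = 1 + Σₖ P(Xᵢ ≥ k + 1 | θ) is evaluated at multipliers
(1, 1.5, 2, 2.5).  Continuous thresholds must increase by more than 1e-6
per step (a flat curve means invalid parameters).  Integer cut-offs round
half away from zero — the unique rule consistent with all four published
threshold/cut-off pairs.  Classification uses half-open intervals with
inclusive lower bounds (healthy < c₁ ≤ mild < c₂ ≤ moderate < c₃ ≤ severe
< c₄ ≤ extremely severe); the top two classes pool into
`severe_or_extreme` by default for group comparisons, where the extreme
class is small, and the unpooled five-class assignment is always retained
in the JSON bundle.

## Validation battery

ANOVA is computed from (n, mean, SD) group summaries — sufficient
statistics for the between/within sums of squares — so raw-data and
summary-mode results agree to machine precision; η² = SSB/(SSB + SSW)
matches the effect-size convention of the severity-group tables.
Tukey–Kramer uses MSW with the unequal-n standard error and
studentized-range p-values.  Linear contrasts use the classical unscaled
integer coefficients (−3, −1, 1, 3 for four groups) with the Σc²/n
standard error; groups keep raw coefficients under unequal n.  MANOVA
computes Wilks' Λ = det(W)/det(W + B) with Rao's F approximation and
requires raw data (cross-product matrices are not recoverable from
univariate summaries).  χ² is Pearson's without continuity correction —
the convention under which the published 2×4 tables reproduce exactly —
with Cramér's V = √(χ²/(N·min(r−1, c−1))).  Cohen's d uses the pooled SD.
No multiple-testing correction is applied across the five trait ANOVAs
(matching the reproduced analysis); Tukey adjustment applies only within
post hoc families.  Empty or n < 2 severity groups are kept in
descriptives but excluded from tests with a logged warning.

## Synthetic data

The generator draws θ ~ N(mean, SD) (default standard normal) and GRM
responses from the shipped calibration, so it doubles as the
parameter-recovery fixture.  Covariates are linear in θ with Gaussian
noise, clipped to the instrument range (1–5 for traits, 18–81 for age), or
Bernoulli with a logistic link.  One seed drives a splittable generator
(numpy `SeedSequence.spawn`), so adding or removing covariates never
perturbs the response stream.

Default covariate effects are **illustrative**, chosen once to match the
qualitative pattern of the reported severity-group contrasts: positive
trait slopes ~0.3–0.45 per latent SD for negative affectivity,
detachment, dissociality and disinhibition; zero slopes for anankastia
and sex (the two null covariates, used for type-I-error calibration);
a negative age slope; binary intercepts matching reported marginal
prevalences (relationship ≈ 65 %, diagnosis ≈ 8 %, psychotherapy ≈ 13 %).
They are not estimates of any population.  Clipping continuous covariates
(rather than resampling) slightly attenuates the implied correlations;
this is accepted for simplicity.

What the generator does **not** emulate: local dependence or method
effects among items, two-factor structure, non-normal latent
distributions, response styles, and covariate–covariate dependence beyond
the shared θ.  Passing tests therefore demonstrate the pipeline's
correctness under its own model assumptions, not robustness to their
violation in real data.

## Problem sizes and stochastic checks

Simulation-based tests use cohort sizes the package's own analyses use:
n = 530 (the study scale), n = 2000 for parameter recovery (10 seeds;
slope correlation > 0.9, median absolute threshold error < 0.15), and
n = 5000 for end-to-end cut-off stability (10 seeds).  Null-calibration
checks run 1000 cohorts of n = 530 and assert type-I error within
[0.03, 0.07] at α = 0.05 for ANOVA (on the zero-slope anankastia trait)
and χ² (on the zero-slope sex indicator).

## Known limitations

* The end-to-end integer cut-off (32, 36, 40, 44) reproduction at
  n = 5000 is intrinsically marginal for the θ = 2 threshold: the
  generating value 40.38 lies 0.12 points below the 40.5 rounding
  boundary, while the sampling SE of the fitted curve at θ = 2 is ≈ 0.2 —
  at the Fisher-information bound for this design, so no estimator can do
  materially better.  Roughly a third of seeds round that threshold to 41.
* The Vuong distinguishability p-value is approximate (see above).
* Item-parameter standard errors, differential item functioning, and
  multidimensional models are out of scope.
* Limited-information fit indices for the IRT models (RMSEA/CFI/TLI) and
  categorical-data CFA fit indices are not implemented; the
  unidimensionality decision rule is: one factor by parallel analysis AND
  MAP.
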
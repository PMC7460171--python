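# Methods

## Model

Two per-subject outcomes are modelled jointly: the internet-addiction total
y1 (Y-IAT, 20–100) and the smartphone-addiction total y2 (SAS, 33–198).
Each margin is a two-parameter regression family —

* normal: `y ~ N(x'β, σ)`, identity link;
* log-normal: `log y ~ N(x'β, σ)`, so β are multiplicative effects and σ is
  the log-scale SD;
* gamma: mean `exp(x'β)` with constant shape α (log link), so the
  coefficient scale matches the log-normal margin —

and the margins are coupled by a bivariate Gaussian or Student-t copula.
The joint log-likelihood is the sum of the two marginal log-densities plus
the copula log-density evaluated at the probability integral transforms
(PITs) `u_ij = F_j(y_ij | x_ij)`. The t copula adds symmetric tail
dependence that strengthens as ν decreases and collapses to the Gaussian
copula as ν → ∞; both families share Kendall's τ = (2/π) arcsin ρ, which the
sampler tests exploit.

Link choices are the canonical ones and are consistent with the magnitude of
the published coefficients (~0.005 per questionnaire point on a log scale).
Covariate effects on the dispersions or on the copula parameter are out of
scope, as are more than two outcomes and non-ignorable missingness.

## Estimation and inference

Fitting is staged for reproducibility. The two margins are first fitted
independently (least squares is exact for the normal and log-normal margins;
the gamma margin is maximized numerically from a log-scale least-squares
start), the copula is fitted to the resulting PITs, and this
inference-functions-for-margins point warm-starts a joint BFGS refinement of
all parameters on unconstrained transforms (log σ, log α, atanh ρ,
log(ν − 2)). The score is analytic — margin score functions and the
closed-form derivatives of both copula log-densities in (u1, u2, ρ) — except
for two partials with no closed form (the shape derivative of the
regularized incomplete gamma and the ν derivative of the t PIT), which use
central differences. The final point is accepted only if it does not
decrease the likelihood relative to the warm start, so likelihood ascent
holds by construction.

Standard errors are the square roots of the diagonal of the inverse observed
information, computed as the (symmetrized) negative Jacobian of the analytic
score at the optimum on the original parameter scale; an information matrix
that is indefinite or has condition number above 1e12 is treated as singular
and the fit is flagged `se_available = False` (estimates are still
returned). Wald p-values use the normal reference distribution. The
confidence interval for ρ uses the Fisher z transform with the delta-method
SE `SE_z = SE_ρ / (1 − ρ²)`, keeping the interval inside (−1, 1). PITs are
clamped to [1e−10, 1 − 1e−10] before the copula term; clamps at the optimum
are counted and logged.

For the t copula the degrees of freedom default to the value chosen by the
rank-based family-selection stage and are then held fixed during the
regression (the two-stage flow: select, then regress); joint estimation of ν
is available via `df_mode="estimated"`. Family selection profiles ρ over the
ν grid {2.1, 3, 4, 5, 6, 8, 10, 15, 20, 30} and then refines (ρ, ν) by
Nelder–Mead; the Gaussian and t fits are compared by AIC with k = 1 and 2
free parameters respectively, ties going to the Gaussian. Pseudo-
observations use rank/(n + 1) with average ranks on ties.

Copula CDF values are computed by 128-node Gauss–Legendre quadrature of the
closed-form conditional CDF (normal, and scaled t with ν + 1 degrees of
freedom), vectorized over evaluation points. This is accurate to ~1e−7
(cross-checked in the tests against `scipy.stats.multivariate_normal.cdf`
and against the elliptical orthant identity C(½, ½) = ¼ + arcsin(ρ)/2π) and
fast enough for the parametric bootstrap, where the per-point Fortran/QMC
routines in scipy are not.

The goodness-of-fit statistic is the Cramér–von Mises distance between the
empirical copula and the fitted parametric copula at the observed
pseudo-observations, with a parametric bootstrap p-value (default 500
resamples; the t-copula ν is held at its fitted value during bootstrap
refits to keep the cost linear in the resample count). Fewer than 50
resamples triggers a warning, not an error.

## Model comparison and covariate selection

Independence-assuming benchmarks come in an LM mode (least squares: normal
margins on the raw scale, log-normal margins via least squares on the log
scale, which coincides with their MLE) and a GLM mode (log-normal or gamma
margins by per-outcome MLE). Their total AIC is the sum of the two
single-outcome AICs, computed with the same likelihood conventions as the
joint model so the comparison is exact; the default comparison grid holds
twelve candidates (4 LM, 4 GLM, 4 copula rows). Backward elimination
removes one covariate from one margin per step — the removal with the
greatest decrease of the joint model's AIC, refitting the full joint model
for every candidate — and stops when no removal helps, so the trace AIC is
non-increasing and rerunning from the final model yields an empty trace.

## Synthetic-data generator

The generator reproduces the study conditions: n = 555 complete cases (or
714 recruited with outcome pairs deleted completely at random at rate
159/714 when missingness is requested), the published psychosocial means,
SDs and correlations, and outcomes drawn from the copula regression itself
with the published final-model coefficients, log-normal IAT dispersion
σ = 0.346, gamma SAS shape α = (80.25/27.94)² ≈ 8.25 (so the SAS mean and
SD match their published values at the covariate means) and a t copula with
ρ = 0.364, ν = 3.

Design choices where the publication is silent:

* **Psychosocial block.** Questionnaire totals are non-negative integers
  with skewed distributions (e.g. depression mean 7.46, SD 7.82), so a
  clipped normal cannot reproduce the published means. The block is
  generated NORTA-style: a latent Gaussian copula feeds gamma margins
  matched to each score's mean/SD, and the latent correlations are solved
  (via the Hermite expansion of the quantile transform) so the *realized*
  Pearson correlations hit the published matrix; scores are then rounded to
  integers. User-edited correlation matrices are projected to the nearest
  PSD matrix by eigenvalue clipping.
* **Usage hours** (weekday/weekend gaming, internet, smartphone) are
  log-normal with log-means 0.0–1.2 and log-SDs 0.6–0.7 — right-skewed,
  typically 1–4 h/day — rounded to one decimal; the study prints no
  usage-hour summaries. Alcohol and smoking rates default to 12% and 6%
  (plausible for Korean middle-schoolers); birth year is a fair draw from
  {1998, 1999} (ages 14–15 at survey time) and enters all models centered
  at its sample mean.
* **Intercepts** are derived, not free: on the log scale,
  `β0 = log(target mean) − σ²/2 (log-normal only) − β'E[x] − ½ β'Σβ`, where
  Σ is the covariate covariance implied by the config. The last term is the
  log-normal-approximation correction for E[exp(β'x)]; without it the
  realized outcome means overshoot their targets by 1–2%.
* Outcome totals are kept continuous (the marginal models are continuous);
  item-level simulation and informative missingness are not modelled. The
  generator also does not correlate usage hours with the psychosocial
  block — no such correlations are published — so passing recovery tests
  here does not certify behaviour under covariate structures the generator
  does not produce (e.g. strong usage–psychopathology confounding).

Regeneration with the same (config, seed) is byte-identical; all
randomness flows through `numpy.random.Generator` objects derived from a
single seed.

## Interface

The package is an analysis library, not a shell tool: the numbered scripts
under `analysis/` are thin narrative drivers over the library functions, and
`run_pipeline` executes the same workflow from a single YAML/dict config, so
no separate command-line interface is provided.

## Problem sizes and numerical choices

The test suite and acceptance script use the sizes natural to the study:
n = 555 for study-sized checks (marginal recovery, copula-family selection
over 100 replicates, Wald coverage and AIC dominance over a shared
100-replicate fixture), n = 5000 for the single high-precision joint refit,
n = 1e5 for moment and Kendall-τ checks of the generator, and a reduced
bootstrap (100 resamples, n = 120, 200 replicates) for the goodness-of-fit
size check. Quadrature tolerances: marginal densities integrate to 1 within
1e−6, copula densities within 1e−4, CDF/quantile round trips within 1e−10.
Optimizer defaults: BFGS with gtol 1e−8 (margins 1e−9) and
method-of-moments/least-squares starts; degenerate samples (zero variance)
raise rather than return boundary estimates; comonotone dependence is
capped at |ρ| ≤ 0.99999 and flagged as a boundary fit.

## Known limitations

* Wald inference is first-order; at n = 555 with 28 parameters the
  aggregate 95% interval coverage in the recovery tests sits near but not
  exactly at nominal (the suite requires ≥ 94%).
* The GoF bootstrap holds ν fixed during refits, slightly understating the
  selection uncertainty of the t copula.
* The CDF quadrature conditions on the first coordinate, so C(u1, u2) and
  C(u2, u1) agree only to ~1e−6 (the densities are exactly exchangeable).
* Only bivariate elliptical copulas are implemented — no Archimedean
  families, rotations or vines; margins in the regression are restricted to
  normal/log-normal/gamma.
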
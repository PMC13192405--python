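# Methods

## Model and estimation

The mixed-effects location-scale (MELS) model gives subject *i* a random
location `v_i` in the mean sub-model `y_ij = β₀ + v_i + ε_ij` and a random
scale `ω_i` in the log-linear within-subject variance sub-model
`σ²_ij = exp(τ₀ + ω_i)`; `(v_i, ω_i)` is bivariate normal with SDs
`(σ_v, σ_w)` and correlation `ρ`.  Estimation is marginal maximum
likelihood.  Internally the random effects are written through the
Cholesky map `v = s₁₁θ₁`, `ω = s₂₁θ₁ + s₂₂θ₂` with `θ ~ N(0, I₂)`, so
every optimizer iterate implies a valid covariance and the standardized
effects `θ` are the quantities whose posterior means we report as
empirical-Bayes (EB) estimates.  Standardizing through the Cholesky factor
(rather than dividing EB means of `(v, ω)` by their SDs) is what makes the
estimates well-defined z-score-like quantities when location and scale
correlate.

Because the within-subject model is Gaussian with a per-subject variance,
subject *i* enters the likelihood only through `(n_i, ȳ_i, SS_i)`.  The
two-dimensional integral per subject is computed by adaptive Gauss–Hermite
quadrature: a damped Newton search (analytic gradient and Hessian,
vectorized across subjects) finds each subject's posterior mode, the local
curvature rescales the Gauss–Hermite grid, and the weighted log-sum-exp
gives the marginal log-likelihood.  The outer optimizer is L-BFGS-B on
`(β₀, τ₀, s₁₁, s₂₁, s₂₂)` with method-of-moments starting values and two
jittered restarts.  A fit is *converged* only if the projected-gradient
∞-norm of the mean per-subject negative log-likelihood is ≤ 1e-5, the
finite-difference observed information is positive definite, no Cholesky
diagonal sits at its 1e-4 lower bound, and the iteration cap (500) was not
hit.  Non-convergence is a return value, never an exception, so
Monte-Carlo drivers can tally convergence fractions.

Numerical choices: quadrature defaults to 15 points per dimension
(`n_quad`); Monte-Carlo drivers fit with 5 (`n_quad_fit`) — with
posterior-mode re-centering the 5-point rule agrees with the 25-point rule
to ~1e-2 log-likelihood units on full-size replicates, far below parameter
noise, and cuts a fit to ~0.2 s.  Exponents are clipped at `exp(80)` to
keep extreme line-search excursions finite.  EB posterior means/SDs come
from the same adaptive grid; plausible values resample the grid nodes with
their normalized posterior weights plus Gaussian jitter of SD
(node spacing)/√12 (the uniform-cell equivalent), so draw moments converge
to the EB moments; a Laplace-Gaussian sampler is available behind
`method="laplace"`.

### Non-existence of the MLE with constant subjects

If any subject has zero within-person variation (`SS_i = 0`, common after
coarse ordinal discretization), the marginal likelihood is unbounded:
integrating the location analytically, that subject's contribution grows
like `exp((n_i−1)²σ_w²/8)` as `σ_w → ∞`, which dominates the `−log σ_w`
decay of the regular subjects.  No MLE exists.  `fit_mels` detects this and
declares non-convergence immediately — this is the "computational
instability" that short rating scales induce, made exact.  A consequence:
the ordinal convergence filter retains precisely the replicates without
constant subjects, and the retained fraction rises steeply with the number
of categories (a few percent at K=5 to ≈20–50% at K=8, depending on the
calibrated log-scale spread).

## The simulated world

Subject truths are independent normals: `Mean_i ~ N(0, sd_location²)`,
`STD_i ~ N(0, sd_logscale²)`, `Error_i ~ N(0, sd_error²)`; the stage-2
outcome is `y_i = β₁Mean_i + β₂STD_i + Error_i` (defaults β₁ = β₂ = 0.5)
and occasion-level data are `y_ij = R_ij·exp(STD_i) + Mean_i`.  Note
`STD_i` is a *log* within-person SD.  Defaults `sd_location = 1`,
`sd_error = 1`.

`sd_logscale` is the one load-bearing quantity the design leaves open: it
controls the ratio of within-subject noise `exp(2·STD_i)/n_i` to
between-subject signal, hence all attenuation magnitudes.  `calibrate_dgp`
sweeps a grid (0.2–0.7) and picks the value whose unbalanced-design SCF
mean-coefficient biases best match the reference pattern
(−0.085/−0.068/−0.053 at the 75:25/50:50/25:75 splits), using common
random numbers across grid values so the comparison reflects the
parameter, not replicate noise.  At high precision the sweep selects
**0.7** (grid SSE 1.1e-4 vs 2.3e-4 at 0.6); an errors-in-variables
back-of-envelope agrees: matching −0.085 requires
`E[exp(2·STD)] ≈ 2.5`, i.e. `sd_logscale ≈ 0.67`.

Missingness: MCAR masks records by independent Bernoulli draws.  MAR uses
a record-level logistic model on the subject's true log-scale,
`P(missing) = expit(α₀ + slope·STD_i)` with `slope = 1` and `α₀` solved by
root-finding so the expected marginal rate hits the target; subjects never
lose every record (masks are redrawn).  This is the simplest mechanism in
which missingness depends only on subject-level variability — observable
in principle, so full-likelihood fitting remains valid while summary
statistics do not.

Ordinal discretization (default `method="round"`): the latent value is
shifted so the population mean sits at the scale midpoint `(1+K)/2`,
rounded to the nearest level and clamped at 1 and K — rating a latent
quantity on a bounded Likert scale with unit-width bins.  More categories
mean a wider range and less ceiling/floor censoring, which is what drives
the monotone-in-K improvement of both methods.  Equal-mass quantile
binning is available (`method="quantile"`, thresholds frozen from a large
reference simulation) but compresses the 1..K scale relative to the latent
scale and therefore distorts the mean coefficient non-monotonically in K;
it is not used by the scenario harness.

## Stage-2 regressors and inference

The variability truth `STD_i` lives on the log-SD scale, so both methods
supply a log-SD regressor:

- **SCF**: iMean and `log(iSD)`.  Exact-zero SDs (ordinal constant
  subjects) floor at `1/√n_i`, the smallest positive sample SD detectable
  from `n_i` integer-spaced values, before the log.  Raw iSD is available
  (`scf_variability="sd"`) but is structurally attenuated (~50%) against a
  log-scale truth for *any* `sd_logscale` — the nonlinearity
  `cov(STD, e^STD)/var(e^STD)` caps its slope — and is kept only as a
  sensitivity flag.
- **MELS**: `β̂₀ + ŝ₁₁θ̂₁` for location and `(τ̂₀ + ω̂_i)/2` for
  variability, where `ω̂_i = ŝ₂₁θ̂₁ + ŝ₂₂θ̂₂` (Eq.-4 scale effects are
  log-variances, so ω/2 is the commensurate log-SD).  Regression on joint
  posterior means is unbiased by the tower property when the fitted
  parameters are correct, which is why EB regressors attain near-nominal
  coverage.  A `standardized=True` flag returns raw `θ̂` for z-score-scale
  comparisons.

Stage-2 inference is OLS with intercept and t-based 95% CIs (n−3 df).  A
plausible-value mode refits across posterior draws and pools by Rubin's
rules; it is optional because the headline tables reflect point-estimate
regressors.

## What a green test establishes — and known gaps

The generator emulates: Gaussian subject truths, conditionally Gaussian
occasions, independent occasions within subject, missingness ignorable
given subject-level variability, and censored-rounded ordinal scales.  It
does **not** emulate autocorrelated within-subject errors, time trends,
MNAR mechanisms, or covariate structure; green tests say nothing about
those.

Two reference quantities are not reproducible under any single calibrated
generator, and their acceptance tests are deliberately red rather than
tuned:

- *Scale-coefficient coverage at coefficient ratio 4.0* (reference 94.2%):
  we measure ≈ 90%.  The estimated location-scale correlation (SE ≈ 0.06
  at 300 subjects) rotates the EB regressor basis; with β₁ = 2 that
  rotation leaks the large mean coefficient into the scale coefficient's
  replicate dispersion (~20% above the nominal OLS SE).  The reference
  table shows the mirror-image anomaly on its *location* row (79.6%
  coverage with bias −0.015, impossible under nominal OLS SEs), so the
  excess dispersion is real in that pipeline too — it just lands on the
  other coefficient.
- *Ordinal K=5 SCF variability coverage* (reference 23.0%): that value
  requires heavy attenuation of the ordinal variability regressor, which
  the stated DGP produces only at `sd_logscale ≈ 0.3` — incompatible with
  the attenuation pattern the calibration matches (`≈ 0.7`).  Under the
  calibrated generator, ordinal censoring *compresses* the regressor and
  inflates rather than attenuates its slope.  One generator cannot satisfy
  both references; the calibration target takes precedence.

Relatedly, the headline "model-based coverage exceeds summary-statistic
coverage for the variability coefficient in every condition" holds
decisively where estimation error is large (unbalanced counts: 96.0 vs
87.3; large variability coefficient: 95.3 vs 87.3) but shrinks to a
statistical near-tie in the missingness conditions (30% MAR at 500
replicates: 93.6 vs 92.6) and reverses for K=8 ordinal — a consequence of
the log-scale summary regressor used here being better behaved than a raw
SD.  For the *mean* coefficient the model-based advantage is large in
every unbalanced or missing-data condition.

## Degenerate and edge inputs

Subjects with a single observed record have an undefined sample SD: they
are flagged (NaN, with a warning) and excluded from stage-2 rather than
silently imputed.  Datasets where every subject is constant cannot
identify the scale model (non-convergence, as above).  Replicates whose
stage-2 regressors are constant or collinear raise with a diagnostic and
are dropped and counted by the driver.  All generators draw from
per-replicate `SeedSequence` substreams of the master seed; reruns with
the same seed are bit-identical, and SCF and MELS always see byte-identical
replicate data.
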
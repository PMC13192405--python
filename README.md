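# melsim

Ecological momentary assessment (EMA) studies ask whether a person's
*typical level* and *moment-to-moment variability* in a repeatedly measured
state — affect, activity, sleep — predict subject-level outcomes.  The
conventional route computes each subject's arithmetic mean (iMean) and
sample standard deviation (iSD) and feeds them into a second-stage
regression.  Those summary statistics are estimates, not truths: they carry
sampling error that grows as a subject contributes fewer occasions, and
feeding them into a regression attenuates its coefficients and corrupts its
confidence intervals (classical errors-in-variables).

`melsim` implements the model-based alternative — the **mixed-effects
location-scale (MELS) model** — together with a Monte-Carlo harness that
quantifies exactly how much better (or worse) each route does across
realistic EMA pathologies: unbalanced observation counts, MCAR and MAR
missingness, and short ordinal rating scales.

## The model

For subject *i* at occasion *j*:

```
y_ij   = β₀ + v_i + ε_ij,        ε_ij ~ N(0, σ²_ij)
σ²_ij  = exp(τ₀ + ω_i)
(v_i, ω_i) ~ N₂(0, Σ),   Σ = [[σ_v², ρσ_vσ_w], [ρσ_vσ_w, σ_w²]]
```

The random location `v_i` is the subject's deviation from the grand mean;
the random scale `ω_i` lets each subject have their own log within-person
variance.  The marginal likelihood is maximized with adaptive Gauss–Hermite
quadrature (per-subject posterior-mode re-centering; the Gaussian
within-subject model reduces each subject to sufficient statistics, so a
300-subject fit takes a fraction of a second).  Per subject the package
returns **standardized empirical-Bayes estimates** — posterior means of the
Cholesky-standardized effects `θ₁, θ₂` (z-score-like, and well-defined even
when location and scale correlate) — with posterior SDs, plus *plausible
values* (posterior draws) for uncertainty propagation into stage-2 models.

The two-stage simulation world: subject truths `Mean_i`, `STD_i` (a log
within-person scale) and `Error_i` are independent normals,

```
y_i  = β₁·Mean_i + β₂·STD_i + Error_i       (β₁ = β₂ = 0.5)
y_ij = R_ij·exp(STD_i) + Mean_i,  R_ij ~ N(0,1)
```

and each method's subject-level (mean, variability) estimates are regressed
on `y_i` to measure the bias and 95% CI coverage of `β̂₁, β̂₂`.

## Worked example

```bash
python examples/04_bias_coverage_study.py
```

runs one design cell (300 subjects, 75% with 10 occasions / 25% with 30,
100 replicates) and prints:

```
method  bias(mean)  bias(var)  cover(mean)  cover(var)
SCF         -0.088     -0.047        65.0%       91.0%
MELS        -0.001     -0.000        95.0%       96.0%
```

Read: the summary-statistic regressors are attenuated — the mean
coefficient lands at 0.412 instead of 0.5 and its 95% CI captures the truth
in only 65% of replicates — while the EB regressors are essentially
unbiased with nominal coverage.  The other examples cover data simulation
(`01`), a single model fit (`02`), shrinkage on matched subjects with 5 vs
40 occasions (`03`), and plausible-value pooling (`04`→`05`).

## The full study

`melsim.SCENARIOS` holds all 18 design cells: three 10-vs-30 observation
splits, five mean-to-variance coefficient ratios, three MCAR and three MAR
missingness levels, and 5–8-category ordinal scales (where fits on
replicates containing zero-variance subjects are — provably — non-estimable
and are tallied as non-converged; `run_condition` implements the
convergence-filter retry protocol).  `calibrate_dgp` fixes the one DGP
quantity the study design leaves open, the spread of the true log-scales,
by matching the attenuation pattern of the unbalanced-design reference
biases.

`scripts/acceptance.py` re-runs the headline numbers end to end — calibrate,
then five design cells at 200 replicates each, recording the coverage of
the stage-2 mean/variability coefficients for each method:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~4 minutes on one CPU; the JSON maps target ids to the recomputed
coverage percentages and the replicate counts behind them.)
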
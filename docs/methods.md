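# Methods

## Scope and data model

The package models weekly body-weight trajectories of meat chickens from
hatch (week 0) to slaughter (week 6) with five parametric sigmoidal
families and a single-predictor adaptive hinge-spline (MARS) regressor,
scores fits with least-squares criteria, and ranks models by information
criteria. The atomic observation is one weighing: optional bird id, age in
weeks, weight in grams. All curves rise from a hatch weight of ~45–85 g
toward an asymptote `A` interpreted as mature weight; with data ending at
six weeks the asymptote is an extrapolation and is weakly identified — a
point that matters repeatedly below.

## Curve forms and resolved ambiguities

The five families and their inflection formulas are tabulated in the README
and in `growth_models.py`. Several published renderings of these equations
are typographically ambiguous; the implementation fixes each to the unique
reading consistent with the model's own printed weekly predictions:

* logistic is `A/(1 + b e^{-kt})` — the age-0 prediction must equal
  `A/(1+b)` (82.32 g with the reference parameters);
* Weibull is `A − b e^{-k t^λ}` — age 0 gives `A − b` (64.20 g);
* Hossfeld is `A(1 + b1 t^{-b2})^{-1}`, with `Y(0) = 0` by continuity
  (`t^{-b2}` diverges at 0); its inflection time is
  `[b1(b2−1)/(b2+1)]^{1/b2}`, the only candidate reading that reproduces the
  reported 6.074 weeks;
* von Bertalanffy uses `e^{-kt}`; a positive exponent would decay away from
  `A` instead of growing toward it.

Two reported values are *not* reproducible from the reported parameters and
are deliberately not matched: the Weibull inflection weight (the formula
gives 5226.3 g, not the printed 6851.3 g) and the weekly spline predictions
at weeks 4 and 6 (the printed equation gives 1011.50 / 2161.96 g, not the
printed 1021.00 / 2191.96 g). The code follows the formulas.

## Fitting

Bounded multi-start nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective). The loss is unweighted OLS on weights in grams;
relative residuals are available (`FitConfig(relative_residuals=True)`) for
heteroscedastic per-bird data but off by default, since the reproduction
path fits weekly means.

Starting values are deterministic: `A₀ = 1.2 × max(weight)`; the
initial-size parameter from the earliest observation (`b₀ = A₀/y₀ − 1`
logistic, `−ln(y₀/A₀)` Gompertz, `A₀ − y₀` Weibull,
`1 − (y₀/A₀)^{1/3}` von Bertalanffy); rate constants from the family's
log-linearization regressed on per-age mean weights; shape parameters at
fixed textbook values (`λ₀ = 2`, `b1₀ = 10`, `b2₀ = 2`). Eight additional
seeded starts perturb each coordinate log-uniformly by up to ×/÷3 — Weibull
and Hossfeld have flat, correlated likelihoods on seven points and a single
start can stall. Bounds keep every inflection formula defined:
`A ∈ (max w, 50 max w)`, `k ∈ (10⁻⁶, 10)`, `λ, b2 ∈ (1+10⁻³, 10)`, von
Bertalanffy `b ∈ (0, 1)`. Stopping: relative cost change < 10⁻¹⁰ or
gradient norm < 10⁻⁸, at most 500 function evaluations per start. The
lowest-SSE converged start wins; identical seeds give bit-identical fits.

Datasets need at least `n_params + 1` distinct ages and a non-constant
weight vector; violations raise before any optimizer runs. In the
five-family driver (`fit_all`) a per-family failure is recorded in its
result rather than raised, so one ill-posed family cannot sink a report.

## MARS

Single predictor (age), additive, degree 1 — the configuration the weekly
weighing problem needs. Candidate knots default to the distinct observed
ages: with seven weekly weighings those are the only locations the data can
distinguish, and the choice makes builds deterministic. A seeded
uniform-random knot grid (`knot_strategy="random"`) is provided for
fidelity to the classical algorithm. The forward pass adds the mirrored
hinge pair minimizing RSS (exact OLS refit each step; a side that is
numerically collinear on the data is dropped, so models need not be fully
paired); ties break toward the smaller knot, above before below. The
backward pass greedily deletes the term whose removal hurts RSS least and
returns the deletion-sequence member minimizing GCV with effective size
`M(λ) = #coefficients + d × #knots`, `d = 2` by default (the usual additive
convention; the source never states its value, so it is configurable).

Small-sample caveat: with `n = 7` and `d = 2`, any model with ≥ 2 knots
already has `M(λ) ≥ n` and an undefined (infinite) GCV, so default pruning
cannot retain the 3–4-knot shape the weekly means clearly carry. Fitting
handfuls of points therefore uses `gcv_penalty_per_knot = 0` (pure
coefficient counting), as in the README example; the default stays `d = 2`
for realistically sized flocks.

## Criteria

`MSE = SSE/n` (the degrees-of-freedom variant `SSE/(n−k)` is exposed as
`mse_df` but not used for ranking), `R² = 1 − SSE/SStot` (the
variance-decomposition form; the alternative regression-sum form disagrees
under biased predictions and would not support "highest R²" selection),
adjusted R² with the conventional `n − k − 1` denominator,
`AIC = n ln(SSE/n) + 2k` and `BIC = n ln(SSE/n) + k ln n` with `k` counting
only curve parameters. `BIC − AIC = k(ln n − 2)` is an exact identity and is
asserted in tests. A zero-SSE fit reports AIC/BIC as a `−inf` sentinel with
a `perfect_fit` flag; a constant observed vector is an error (R² undefined).

The reference study's fitted parameter table and its MSE/AIC/BIC/R² values
cannot be reproduced from any published data: they derive from unpublished
per-bird records (its AIC/BIC pairs imply non-integer effective `n` of
roughly 7.9–8.8, inconsistent with the seven printed means). The package
therefore treats the reported parameters as evaluation inputs and replaces
value-matching with property checks: a fresh Gompertz fit on the seven
means must achieve SSE no worse than the reported parameters achieve on
those same means, the reported criterion values must rank Gompertz first
and Hossfeld last, and simulated-flock round trips must recover generating
parameters (below).

## Synthetic flocks

`simulate` emulates the study design: `n_birds` weighed at fixed weekly
ages. Biological heterogeneity enters through a per-bird asymptote
`A_i = A(1 + cv_A z_i)` — the simplest exchangeable structure, since no
covariance information is published to justify more — and measurement error
is multiplicative, `(1 + cv_ε ε)`, because weights span ~50 g to ~2200 g and
constant-CV error is the realistic default; an additive fixed-SD option
exists for textbook OLS experiments. Weights are floored at 1 g so extreme
hatch-week draws stay positive (a deliberate, documented deviation from
pure Gaussianity). Defaults: 192 birds, ages 0–6, `cv_A = 0.08`,
`cv_ε = 0.05` — flock size and design from the study; the two CVs are
typical within-flock broiler variation, chosen once. The simulator is a
pure function of its scenario (seeded `numpy` Generator).

What the generator does *not* emulate: growth beyond six weeks, sex or
feed-intake covariates, serial correlation within a bird beyond the shared
asymptote, and mortality. Passing recovery tests therefore show correctness
of the estimator under the assumed noise structure, not robustness to real
longitudinal dependence.

## Verification problem sizes and numerical choices

Noise-free round trips use the reported parameters at weeks 0–6 (weeks 1–6
for Hossfeld, whose curve is exactly 0 g at age 0 and hence not a valid
weight record); recovery is to ~10⁻¹⁴ relative, asserted at 10⁻³ (10⁻² for
the mutually trading Weibull rate/shape). Noisy recovery uses 50 birds ×
7 ages × 20 seeds at 2% multiplicative noise and asserts median signed
relative bias of `Â` and `k̂` below 2% for Gompertz and logistic; the median
absolute error of the Gompertz `Â` is larger (~2.3%) precisely because the
asymptote is an extrapolation. The statistical-structure checks run one
10⁴-bird flock. Hinge-spline oracles (brute-force single-knot search,
independent greedy-deletion GCV sequence, normal-equations and statsmodels
OLS coefficient checks) run on random datasets of 5–20 points. The full
suite runs in well under a minute.

Report tables round half-even to 3 decimals for parameters and criteria and
2 for weights, matching the conventional table layout; report files contain
no timestamps, so identical inputs and seeds reproduce byte-identical
output.

## Known limitations

* No standard errors or confidence intervals for curve parameters, and no
  mixed-effects (per-bird random coefficient) fitting — out of scope.
* `A` estimated from 0–6-week data is an extrapolation; compare families by
  fit criteria, not by their asymptotes.
* MARS is single-predictor and piecewise linear; no interactions, no cubic
  smoothing of the final model.
* GCV with the default per-knot charge is uninformative below ~15
  observations (see the small-sample caveat above).
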
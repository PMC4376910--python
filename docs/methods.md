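# Methods

## Data model and cross-sectional reduction

The observed data per subject are `O = (L0, C_1, L_1, Y_1, …)` on a grid of
measurement times: baseline covariates `L0`, longitudinal covariates `L_jk`
with observedness indicators `C_jk` (the stored value satisfies
`A = C · f_A`: a value exists exactly where its flag is 1), and interval
death indicators `Y_j = I(t_j < T ≤ t_{j+1})` (ties at the upper boundary
fall into that interval; death is absorbing). Continuous covariates are
affinely rescaled to [0,1] using observed entries only
(`rescale_unit_interval`); constant variables are a hard error and must be
dropped by the caller.

Under the Markov assumption — each `L_jk` depends on the past only through
`(L0, L_{j−1})`, and contemporaneous covariates do not interact — the
importance of `L_jk` for `Y_{j'}` reduces to a cross-section on the subjects
still alive at the start of interval `j'`:

```
A = L_jk,  C = C_jk,  W = (L0, C_{j−1}, L_{j−1}),  Y = Y_{j'}.
```

Contemporaneous `L_{jk*}` (`k* ≠ k`) are not confounders and are excluded
from `W`. Missing entries *inside* `W` are zero-filled and the corresponding
flag columns are kept as covariates, so missingness information enters the
adjustment set deterministically, without an imputation model. A
`full_history` option widens `W` to all earlier time points for users who do
not want to lean on the Markov reduction; the lag-1 form is the default
because it is what the structural model implies and it keeps `W` small.

## Parameters

Both parameters are population intervention effects `E(Y^I) − E(Y)` under a
perturbation of the exposure mechanism that also removes missingness
(`C^I = 1`):

* continuous: the conditional density of `A` is translated by `δ`;
  identification gives
  `Ψ_c = E_W E_g[Q̄(A+δ, 1, W) | C=1, W] − E(Y)`.
* binary: `P(A=1|W)` is raised by `δ`, needing `0 < δ < inf_w g(0|1,w)`
  (the infimum is enforced as a strict minimum over the sample — a uniform
  intervention is only well defined if every stratum can absorb the shift);
  `Ψ_b = E_W[Σ_a g*(a|W) Q̄(a,1,W)] − E(Y)` with the contrast
  `Q̄(1,1,W) − Q̄(0,1,W)` entering through `g*`.

The two scales are comparable to first order: both have the form
`a + δ·b` with `b` the appropriate average slope of the outcome regression
in the exposure, and on the shipped worked examples (linear outcome: both
exactly `δ`; logistic outcome at `δ = 0.01`: 0.0019 vs 0.0019) the
agreement is verified numerically by the test suite. Positivity —
`φ(1|w) > 0` and the relevant `g` support conditions — is reported by
`positivity_check`, which flags observations whose fitted denominators fall
below the configured floor.

## Efficient influence function

Writing `m(w)` for the intervened conditional mean, `r` for the relevant
exposure-mechanism ratio (`g(a−δ|1,w)/g(a|1,w)` continuous,
`g*(a|w)/g(a|1,w)` binary), and `s(a,w)` for the shifted outcome-regression
evaluation, the influence function used everywhere is

```
D(O) = (C/φ(1|W)) [ r(A,W)(Y − Q̄(A,1,W)) + s(A,W) − m_g(W) ] + m(W) − Y − ψ,
```

where `m_g` is `m` in the continuous case and the *no-shift* conditional
mean in the binary case. This is the canonical gradient obtained from the
likelihood factorization `Q_W × φ × g × Q`, with inverse-probability-of-
missingness factors attached to every term that is only identified on
observed rows. Its defining properties are enforced by tests rather than
assumed: the empirical mean is exactly zero at the estimating-equation
solution, is mean-zero at the truth under true nuisances, and `Var(D)/n`
matches the replication variance of the EE estimator.

## Estimators

**TMLE.** Starting from initial fits `(Q̄_n, g_n, φ_n)`, each iteration
(1) fluctuates `Q̄` along the logistic submodel
`logit Q̄_ε = logit Q̄ + ε·H`, `H = (1/φ)·r`, with `ε` fit by Bernoulli
maximum likelihood on observed rows; (2) fluctuates the exposure mechanism —
an exponential tilt `g_η ∝ g · exp{η (Q̄(a+δ,1,w) − m(w))}` for continuous
exposures (renormalized on the evaluation grid), a logistic fluctuation of
`g(1|1,w)` with covariate `Q̄(1,1,w) − Q̄(0,1,w)` for binary — with the
tilt likelihood weighted by `C/φ`; (3) recomputes `m(W)` and the EIF. The
procedure stops when `|mean D| < se/log n` (with an absolute floor of 1e−10
for degenerate cases such as `δ = 0`, where the EIF vanishes identically),
or after `max_iter = 20` iterations, in which case the last iterate is
returned with a non-convergence flag. A `iterative=False` switch gives the
one-step version. `φ` is estimated once and held fixed during targeting.
Because the final estimate is a plug-in, the intervened-mean component is
always in [0,1].

**EE.** The EIF is linear in `ψ`, so the estimating-equation estimate is the
explicit mean of `D + ψ` at the initial fits. It can leave the parameter
space; if it does, it is returned with an `out_of_range` flag rather than
truncated.

**Gcomp/IPMW and Unadjusted.** The common-practice comparators: the printed
weighted-plug-in formulas with `Q̄` and `φ` fit by AIC-based bidirectional
stepwise logistic regression (main terms; intercept-only for the unadjusted
version), and a naive influence curve for the standard error (nuisance
estimation ignored). They are consistent only when both parametric models
are right.

All standard errors are `sd(D)/√n`, with Wald 95% intervals and two-sided
normal p-values (reports floor displayed p-values at 0.001).

## Nuisance estimation

Binary regressions (`Q̄`, `φ`, binary-exposure `g`) use a V-fold
cross-validated convex stack. Weights minimize the cross-validated negative
Bernoulli log-likelihood over the probability simplex (SLSQP, uniform start
so ties resolve toward equal weights, with a guard that the stack never does
worse than the best single candidate); squared-error loss is available. The
default library is GLM, stepwise (AIC, bidirectional), ridge-shrunk logistic
(standing in for a weakly informative Bayesian fit), a B-spline GAM
(statsmodels, df 5 per smooth, binary columns linear, new data clipped to
the training range of each smooth), an adaptive hinge-spline learner
(forward least-squares selection of mirrored hinge pairs at marginal
quantile knots, logistic calibration of the selected basis — a pragmatic
small-scale MARS-style learner without backward pruning), and the
intercept-only mean. Folds are stratified on the outcome; `V = 10` by
default (the fold count, the loss, and the stratification are package
choices — nothing forces them). A candidate that throws on any fold is
dropped with a warning; a degenerate response returns a MEAN-only fit.

Conditional densities of continuous exposures are stacks of histogram
estimators over a grid of (bin count ∈ {2, 5, 10, 20}) × (equal-width,
equal-frequency) candidates. Each candidate models bin membership
sequentially (hazard-style: `P(A ∈ bin_b | A ∉ earlier bins, W)` by
main-terms logistic regression, or by the binary stack when configured),
giving bin probabilities that sum to one exactly and a piecewise-constant
density. Stack weights maximize the cross-validated log-density. Density
evaluations used as ratio denominators are floored at 1e−3 to tame
practical positivity violations; evaluations outside [0,1] are zero.

## Numerical choices

* `m(W)` is computed by midpoint quadrature of the fitted density on a
  uniform grid over [0,1] (200 nodes by default, configurable; rows are
  chunked so memory stays bounded at any sample size). For piecewise-
  constant densities this is exact up to edge-alignment error of order one
  grid cell.
* `Q̄(a+δ, ·)` beyond the observed support is evaluated by extrapolating
  the fitted regression — no clipping — while the density ratio is zero
  whenever `a − δ` falls below the support; this preserves the plug-in
  identity. Targeting covariates are capped at 1/floor.
* Probabilities are clipped to [1e−6, 1−1e−6] before logit transforms.
* Fluctuation parameters are fit by bounded scalar likelihood maximization
  (`|ε| ≤ 1` per iteration, `|η| ≤ 20`; iterations compound).

## Synthetic data

The longitudinal generator draws, in temporal order: baseline severity
(Beta(2,2)) and a binary baseline flag; per time point and covariate, an
observedness indicator whose probability worsens with the previous health
state and with previous missingness (scaled by `missingness_strength`; 0
means fully observed); covariate values from Beta distributions (continuous,
concentration 8) or logistic Bernoullis (binary) driven by the own lag and
baseline only — so the Markov property holds by construction, which the
suite checks by a lag-2 regression test; and an absorbing logistic death
hazard driven by the current observed values, baseline severity, and the
missingness flags (defaults give interval death rates of roughly 15–25%,
deliberately event-rich so every cell of a small study is estimable). It
emulates the *structure* the method assumes — informative missingness,
Markov dynamics, discrete-time hazard — not the marginals of any real
trauma cohort; passing tests therefore certify the estimators under the
assumed structure, not performance on real data.

The worked comparability examples are generated exactly as specified above,
with closed-form nuisances (the conditional density of `A1` given `A2`
follows from Bayes' rule on the Beta law). `true_psi` computes every true
parameter value by adaptive quadrature (or seeded Monte Carlo) directly
from the generating law, independently of all estimator code.

The confounded scenario used for the double-robustness grid has a binary
exposure, a continuous and a binary confounder with an interaction in every
mechanism, and informative missingness; coefficients were chosen (by
inspecting the analytic limits of the misspecified estimators, not their
simulated values) so that an intercept-only working model is *materially*
wrong — misspecification bias ≈ −0.03 on a true value of ≈ 0.137 — while
positivity stays comfortable (`φ ∈ [0.20, 0.89]`, `g(1|w) ∈ [0.31, 0.69]`).
"Right" working models are main-terms logistic fits in the provided columns
(which include the interaction product), "wrong" ones are intercept-only.

Simulation sizes used by the acceptance-level tests — 150/120 replicates at
n = 1000 with a {GLM, MEAN} stack for recovery and coverage, 100 replicates
per cell at n = 2000 for the 2×2 grid, 2×10⁶ draws for Monte Carlo truths —
keep the whole suite at desk scale while leaving Monte Carlo standard
errors well below the effects being tested.

## Known limitations

* The exposure kinds are binary or continuous-on-(0,1); no counts or
  categorical exposures.
* No cross-fitting of nuisances and no multiple imputation; missingness is
  handled by inverse weighting and informative-missingness adjustment only.
* No competing risks (discharge is not modelled; death is the only event)
  and no dynamic-regime parameters — effects are per cross-section.
* The histogram density family is piecewise constant; very sharp density
  features interact with the 1e−3 floor and the grid resolution.
* Influence-curve inference is asymptotic; no bootstrap option.
* The hinge-spline learner has no backward pruning and is intended as a
  flexible library member, not a reference spline implementation.
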
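# shiftvim

Doubly robust variable-importance estimation for longitudinal cohorts with
missing exposures.

## The problem

In a discrete-time cohort — the motivating setting is severe-trauma care,
where physiology, coagulation, and treatment variables are measured at
admission and at a handful of follow-up times, and some measurements are
missing precisely because the patient is deteriorating — a clinician wants to
know *which variable, at which time, matters most for death in each upcoming
interval*. Regression coefficients answer this only under a correctly
specified parametric model; machine-learning importance scores answer it
without defining a statistical parameter at all.

`shiftvim` instead defines, for each covariate `L_jk` measured at time `t_j`
and each outcome interval `j' ≥ j`, a **stochastic-intervention variable
importance measure**

```
Ψ = E(Y^I) − E(Y)
```

the change in the interval death rate if the exposure-generating mechanism
were perturbed while everything else is left alone:

* **continuous exposure** (rescaled to [0,1]): every draw of `A` is shifted up
  by `δ`, and the exposure is always observed,

  `Ψ_c = E_W E_g[ Q̄(A + δ, 1, W) | C = 1, W ] − E(Y)`;

* **binary exposure**: `P(A = 1)` is raised by `δ` (requiring
  `δ < inf_w g(0|1,w)`),

  `Ψ_b = E_W[ Σ_a g*(a|W) Q̄(a, 1, W) ] − E(Y)`,
  with `g*(1|w) = g(1|1,w) + δ`.

Here `Q̄(a,c,w) = E(Y | A=a, C=c, W=w)` is the outcome regression, `g` the
exposure mechanism, `φ(1|w) = P(C=1|w)` the missingness mechanism, and
`W = (L0, C_{j−1}, L_{j−1})` the most recent history (a Markov reduction
turns the longitudinal problem into one cross-section per
(variable, time, interval) cell). Missingness is treated as *informative*:
`C` may depend on the previous health state and may itself affect the
outcome.

Both parameters are estimated by

* **TMLE** — targeted minimum loss-based estimation: a plug-in estimate whose
  nuisances are iteratively fluctuated (logistic submodel for `Q̄`,
  exponential tilt for `g`) until the efficient influence function (EIF)
  equation is solved; always respects parameter bounds;
* **EE** — the closed-form estimating-equation solution of the same EIF;
* **Gcomp/IPMW** and **Unadjusted** — common-practice comparators with
  stepwise-logistic nuisances.

TMLE and EE are doubly robust (consistent if either `Q̄` or both `g` and `φ`
are consistently estimated) and locally efficient, with influence-curve Wald
inference. Nuisance regressions are fit by a cross-validated convex stack
(super learner) over {GLM, stepwise, ridge-shrunk logistic, GAM, adaptive
hinge splines, mean}; conditional densities of continuous exposures by a
stack of hazard-regression histogram estimators.

## Worked example

The package ships the two comparability scenarios used to check that the
continuous and binary parameters are on the same scale: `A1 ~
Beta(2,2)·0.8 + 0.1`, `A2 | A1 ~ Bern(A1)`, `Y ~ Bern(expit(A1 + A2))`, no
missingness. Their true values come from quadrature over the generating law:

```pycon
>>> from shiftvim import true_psi
>>> true_psi("worked_logistic", "psi_c", delta=0.01)
0.0018987365719030616
>>> true_psi("worked_logistic", "psi_b", delta=0.01)
0.0019451773539856854
```

A shift of 0.01 on either variable moves the death rate by ≈ 0.0019 — the
two importance measures are comparable to first order (and for a linear
outcome both equal δ exactly). A full synthetic study:

```pycon
>>> from shiftvim import DGPSpec, generate, StudyConfig, run_study, rank_vims
>>> from shiftvim.pipeline import format_estimates
>>> data = generate(DGPSpec(n=800, J=3, K=2, seed=1))
>>> cfg = StudyConfig(sl_library=("GLM", "GAM", "MEAN"), sl_folds=5,
...                   density_grid=((5, "equal_width"), (10, "equal_width")),
...                   n_grid=100, seed=1)
>>> ranked = rank_vims(run_study(data, cfg), alpha=0.05, top=5)
>>> print(format_estimates(ranked).to_string(index=False))
 interval  rank variable  var_time             TMLE               EE      GcompIPMW     Unadjusted
        0     1  x1_bina         0 0.0014 (< 0.001) 0.0014 (< 0.001) 0.0014 (0.923) 0.0014 (0.923)
        2     1  x0_cont         1   0.0225 (0.027)   0.0226 (0.026) 0.0207 (0.307) 0.0209 (0.303)
```

Each row reads: raising the named variable (measured at `var_time`) by 1% of
its range for every at-risk patient would change the death rate in the given
interval by the tabulated amount; only TMLE-significant variables are kept,
ranked by magnitude, with the comparator estimates alongside (note the
efficient estimators detect effects the Gcomp/IPMW p-values miss).

The same pipeline is scriptable from the shell:

```
shiftvim simulate --n 800 -J 3 -K 2 --out-csv study.csv --out-meta meta.tsv
shiftvim run config.yaml --data-csv study.csv --var-meta meta.tsv --out-dir out/
shiftvim evaluate --data-csv study.csv --var-meta meta.tsv -p 0 --out auc.tsv
```

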
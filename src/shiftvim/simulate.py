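"""Synthetic data generators and exact parameter oracles.

Three families of generators:

* :func:`generate` — a longitudinal cohort with the structure the method
  assumes: baseline covariates, Markov longitudinal covariates (each drawn
  from its immediately preceding value and baseline only), *informative*
  missingness (observedness depends on the previous health state and
  previous missingness), and an absorbing discrete-time death hazard that
  depends on the current observed values and missingness flags.
* :func:`generate_worked_example` — the two comparability scenarios: a
  continuous variable A1 ~ Beta(2,2)·0.8 + 0.1 (support [0.1, 0.9]), a
  binary variable A2 | A1 ~ Bernoulli(A1), no missingness, and either a
  linear outcome Y = A1 + A2 or a binary outcome Y ~ Bern(expit(A1 + A2)).
* :func:`confounded_cross_section` — a single cross-section with a binary
  exposure, genuine confounding, informative missingness, and an interaction
  term in every mechanism, used for the double-robustness grid (a main-terms
  or intercept-only working model is misspecified for it).

:func:`true_psi` computes true parameter values by quadrature or Monte Carlo
directly from the generating laws, independent of all estimator code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit, logit

from .data import CrossSection, LongitudinalData, VarMeta
from .vim import (
    ExactConditionalDensity,
    NuisanceSet,
    TrueBinaryExposure,
    TrueOutcomeRegression,
)

__all__ = [
    "DGPSpec",
    "generate",
    "generate_worked_example",
    "worked_example_nuisances",
    "confounded_cross_section",
    "confounded_nuisances",
    "true_psi",
]

_BETA22 = stats.beta(2, 2)


# ---------------------------------------------------------------------------
# longitudinal NPSEM-style generator


@dataclass
class DGPSpec:
    """Configuration of the longitudinal generator.

    ``missingness_strength`` scales the probability of a missing measurement
    (0 means fully observed); ``confounding_strength`` scales how strongly
    previous covariates drive both later covariates and the death hazard.
    ``hazard_coefs`` are (intercept, continuous-value slope, binary-value
    slope, baseline slope, missingness slope) on the logit scale.
    """

    n: int = 500
    J: int = 3
    K: int = 2
    seed: int = 0
    missingness_strength: float = 1.0
    confounding_strength: float = 1.0
    hazard_coefs: tuple = (-2.2, 1.2, 0.8, 0.6, 0.7)
    beta_concentration: float = 8.0
    scenario: str = "trauma_like"


def _var_kinds(K: int) -> list[str]:
    return ["continuous" if k % 2 == 0 else "binary" for k in range(K)]


def generate(spec: DGPSpec) -> LongitudinalData:
    """Sample one longitudinal cohort in temporal order.

    Time 0 measurements are fully observed (admission); for later times each
    variable's observedness depends on the previous values, previous flags
    and baseline, its value on its own previous value and baseline (Markov),
    and the death hazard on the current observed state.  Death is absorbing:
    all later entries are degenerate (flags 0, values NaN, death 0).
    """
    rng = np.random.default_rng(spec.seed)
    n, J, K = spec.n, spec.J, spec.K
    cf, ms, kap = spec.confounding_strength, spec.missingness_strength, spec.beta_concentration
    h0, h_cont, h_bin, h_base, h_miss = spec.hazard_coefs
    kinds = _var_kinds(K)

    b1 = _BETA22.rvs(size=n, random_state=rng)
    b2 = rng.binomial(1, 0.4, size=n).astype(float)
    baseline = pd.DataFrame({"base_sev": b1, "base_flag": b2})

    cov = np.full((n, J, K), np.nan)
    flags = np.zeros((n, J, K), dtype=int)
    death = np.zeros((n, J), dtype=int)
    alive = np.ones(n, dtype=bool)
    prev_val = np.zeros((n, K))  # observed values (0 where unobserved)
    prev_flag = np.ones((n, K))

    for j in range(J):
        cur_val = np.zeros((n, K))
        cur_flag = np.zeros((n, K), dtype=int)
        for k in range(K):
            if j == 0:
                p_obs = np.ones(n)
            else:
                eta = -1.8 + cf * (1.5 * (0.5 - prev_val[:, 0])) \
                    + 0.8 * (1.0 - prev_flag[:, k]) + 0.5 * b2
                p_obs = 1.0 - ms * expit(eta)
            c = rng.binomial(1, np.clip(p_obs, 0.0, 1.0))
            if kinds[k] == "continuous":
                mu = expit(-0.3 + cf * (1.2 * (prev_val[:, k] - 0.5)) + 0.4 * b1)
                val = rng.beta(mu * kap, (1 - mu) * kap)
                val = np.clip(val, 1e-6, 1 - 1e-6)
            else:
                p1 = expit(-0.8 + cf * (1.5 * prev_val[:, k] + 0.6 * prev_val[:, 0])
                           + 0.4 * b2)
                val = rng.binomial(1, p1).astype(float)
            cur_val[:, k] = np.where(c == 1, val, 0.0)
            cur_flag[:, k] = c
        haz = expit(
            h0
            + h_cont * cur_val[:, 0]
            + (h_bin * cur_val[:, 1] if K > 1 else 0.0)
            + h_base * b1
            + h_miss * (1.0 - cur_flag[:, 0])
        )
        dies = rng.binomial(1, haz).astype(bool) & alive
        for k in range(K):
            obs_rows = alive & (cur_flag[:, k] == 1)
            cov[obs_rows, j, k] = cur_val[obs_rows, k]
            flags[alive, j, k] = cur_flag[alive, k]
        death[dies, j] = 1
        alive = alive & ~dies
        prev_val, prev_flag = cur_val, cur_flag.astype(float)

    names = [f"x{k}_{kinds[k][:4]}" for k in range(K)]
    data = LongitudinalData(
        subject_id=np.arange(n),
        baseline=baseline,
        times=np.arange(J, dtype=float),
        covariates=cov,
        miss_flags=flags,
        death=death,
        var_meta=[VarMeta(names[k], kinds[k], "treatment") for k in range(K)],
    )
    data.validate()
    return data


# ---------------------------------------------------------------------------
# worked comparability examples


def _draw_worked(n: int, scenario: str, rng: np.random.Generator):
    a1 = 0.1 + 0.8 * _BETA22.rvs(size=n, random_state=rng)
    a2 = rng.binomial(1, a1).astype(float)
    if scenario == "worked_linear":
        y = a1 + a2
    elif scenario == "worked_logistic":
        y = rng.binomial(1, expit(a1 + a2)).astype(float)
    else:
        raise ValueError(f"unknown worked scenario {scenario!r}")
    return a1, a2, y


def generate_worked_example(
    n: int, scenario: str, seed: int = 0, exposure: str = "continuous"
) -> CrossSection:
    """One worked-example cross-section (no missingness, phi = 1).

    ``exposure="continuous"`` analyses A1 with W = (A2); ``"binary"``
    analyses A2 with W = (A1).
    """
    rng = np.random.default_rng(seed)
    a1, a2, y = _draw_worked(n, scenario, rng)
    ones = np.ones(n, dtype=int)
    if exposure == "continuous":
        return CrossSection(
            W=pd.DataFrame({"a2": a2}), C=ones, A=a1, Y=y,
            exposure_kind="continuous",
            meta={"scenario": scenario, "variable": "a1"},
        )
    return CrossSection(
        W=pd.DataFrame({"a1": a1}), C=ones, A=a2, Y=y,
        exposure_kind="binary",
        meta={"scenario": scenario, "variable": "a2"},
    )


def _a1_pdf(a: np.ndarray) -> np.ndarray:
    return _BETA22.pdf((a - 0.1) / 0.8) / 0.8


def worked_example_nuisances(scenario: str, exposure: str = "continuous") -> NuisanceSet:
    """Exact (Qbar, g, phi) for a worked scenario.

    For the continuous exposure the conditional density of A1 given A2 = a2
    follows from Bayes' rule: p(a1 | a2=1) = a1 f(a1) / E[A1] and
    p(a1 | a2=0) = (1-a1) f(a1) / (1 - E[A1]), with E[A1] = 1/2 by symmetry.
    """
    if scenario == "worked_linear":
        qfn = lambda a, Wm: a + Wm[:, 0]  # noqa: E731
    elif scenario == "worked_logistic":
        qfn = lambda a, Wm: expit(a + Wm[:, 0])  # noqa: E731
    else:
        raise ValueError(f"unknown worked scenario {scenario!r}")
    phi = lambda Wm: np.ones(len(Wm))  # noqa: E731
    if exposure == "continuous":
        def gfn(a, Wm):
            base = _a1_pdf(a)
            w = Wm[:, 0]
            dens = np.where(w > 0.5, a * base / 0.5, (1 - a) * base / 0.5)
            return np.where((a >= 0.1) & (a <= 0.9), dens, 0.0)

        g = ExactConditionalDensity(gfn, n_grid=400)
    else:
        g = TrueBinaryExposure(lambda Wm: Wm[:, 0])
    return NuisanceSet(qbar=TrueOutcomeRegression(qfn), g=g, phi=phi)


# ---------------------------------------------------------------------------
# confounded cross-sectional scenario for the double-robustness grid

_CONF = {
    "phi": (1.2, -2.6, 0.9),             # intercept, W1, W2
    "g": (-0.8, 1.6, 0.7, -1.6),         # intercept, W1, W2, W1*W2
    "q": (-2.2, 1.2, 2.8, 0.6, -1.2, -1.0),  # intercept, a, W1, W2, W1*W2, (1-c)
}


def _conf_phi(w1, w2):
    b = _CONF["phi"]
    return expit(b[0] + b[1] * w1 + b[2] * w2)


def _conf_g1(w1, w2):
    b = _CONF["g"]
    return expit(b[0] + b[1] * w1 + b[2] * w2 + b[3] * w1 * w2)


def _conf_q(a, c, w1, w2):
    b = _CONF["q"]
    return expit(b[0] + b[1] * a + b[2] * w1 + b[3] * w2 + b[4] * w1 * w2
                 + b[5] * (1.0 - c))


def confounded_cross_section(n: int, seed: int = 0) -> CrossSection:
    """Binary-exposure cross-section with confounding and informative missingness.

    W = (W1 continuous, W2 binary, and their product as an explicit column so
    correctly-specified working models are main-terms in the provided
    columns).  The exposure is missing informatively; Y is generated from the
    observed exposure C·A and C itself.
    """
    rng = np.random.default_rng(seed)
    w1 = _BETA22.rvs(size=n, random_state=rng)
    w2 = rng.binomial(1, 0.5, size=n).astype(float)
    c = rng.binomial(1, _conf_phi(w1, w2))
    a_latent = rng.binomial(1, _conf_g1(w1, w2)).astype(float)
    a_obs = np.where(c == 1, a_latent, 0.0)
    y = rng.binomial(1, _conf_q(a_obs, c, w1, w2)).astype(float)
    A = np.where(c == 1, a_latent, np.nan)
    W = pd.DataFrame({"w1": w1, "w2": w2, "w1x2": w1 * w2})
    return CrossSection(W=W, C=c.astype(int), A=A, Y=y, exposure_kind="binary",
                        meta={"scenario": "confounded"})


def confounded_nuisances(
    cs: CrossSection, q_right: bool, gphi_right: bool
) -> NuisanceSet:
    """Parametric nuisance fits for the double-robustness grid.

    "Right" models are main-terms logistic regressions in the provided
    columns (which include the interaction column, so they are correctly
    specified); "wrong" models are intercept-only.
    """
    from .superlearner import _GLMLearner, _MeanLearner

    Wm = cs.W.to_numpy(dtype=float)
    obs = cs.C.astype(bool)
    y = cs.Y.astype(float)

    def fit(X, t, right):
        m = (_GLMLearner() if right else _MeanLearner()).fit(
            X if right else np.empty((len(t), 0)), t
        )
        return m, right

    qm, qr = fit(np.column_stack([cs.A[obs], Wm[obs]]), y[obs], q_right)
    gm, gr = fit(Wm[obs], cs.A[obs].astype(float), gphi_right)
    pm, pr = fit(Wm, cs.C.astype(float), gphi_right)

    def qfn(a, W):
        X = np.column_stack([a, W]) if qr else np.empty((len(a), 0))
        return np.clip(qm.predict_proba1(X), 1e-6, 1 - 1e-6)

    def g1fn(W):
        return gm.predict_proba1(W if gr else np.empty((len(W), 0)))

    def phifn(W):
        return np.clip(pm.predict_proba1(W if pr else np.empty((len(W), 0))),
                       1e-6, 1.0)

    return NuisanceSet(
        qbar=TrueOutcomeRegression(qfn),
        g=TrueBinaryExposure(g1fn),
        phi=phifn,
        meta={"q_right": q_right, "gphi_right": gphi_right},
    )


# ---------------------------------------------------------------------------
# exact parameter values


def _quad_beta(fn) -> float:
    """Integral of fn(b) against the Beta(2,2) density on (0,1)."""
    val, _ = integrate.quad(lambda b: fn(b) * _BETA22.pdf(b), 0.0, 1.0,
                            limit=200)
    return val


def true_psi(
    scenario: str,
    target: str,
    delta: float,
    method: str = "quadrature",
    n_draws: int = 2_000_000,
    seed: int = 0,
) -> float:
    """True VIM value computed directly from the generating law.

    Independent of all estimator code: quadrature integrates the
    identification formula against the exact covariate and exposure laws;
    Monte Carlo draws from the generator and averages the same integrand.
    """
    if target not in ("psi_c", "psi_b"):
        raise ValueError(f"unknown target {target!r}")

    if scenario in ("worked_linear", "worked_logistic"):
        link = (lambda x: x) if scenario == "worked_linear" else expit
        if method == "mc":
            rng = np.random.default_rng(seed)
            a1 = 0.1 + 0.8 * _BETA22.rvs(size=n_draws, random_state=rng)
            a2 = rng.binomial(1, a1).astype(float)
            if target == "psi_c":
                return float(np.mean(link(a1 + delta + a2) - link(a1 + a2)))
            return float(delta * np.mean(link(1.0 + a1) - link(a1)))
        a1 = lambda b: 0.1 + 0.8 * b  # noqa: E731
        if target == "psi_c":
            return _quad_beta(
                lambda b: a1(b) * (link(a1(b) + delta + 1) - link(a1(b) + 1))
                + (1 - a1(b)) * (link(a1(b) + delta) - link(a1(b)))
            )
        return delta * _quad_beta(lambda b: link(1.0 + a1(b)) - link(a1(b)))

    if scenario == "confounded":
        if target != "psi_b":
            raise ValueError("the confounded scenario has a binary exposure")

        def cell(w1, w2):
            g1 = _conf_g1(w1, w2)
            q1 = _conf_q(1.0, 1.0, w1, w2)
            q0 = _conf_q(0.0, 1.0, w1, w2)
            phi = _conf_phi(w1, w2)
            m_b = g1 * q1 + (1 - g1) * q0 + delta * (q1 - q0)
            ey = phi * (g1 * q1 + (1 - g1) * q0) + (1 - phi) * _conf_q(0.0, 0.0, w1, w2)
            return m_b - ey

        return _quad_beta(lambda b: 0.5 * (cell(b, 0.0) + cell(b, 1.0)))

    raise ValueError(f"no exact parameter value for scenario {scenario!r}")
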
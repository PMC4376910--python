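"""The four estimators of each variable-importance parameter.

* :func:`tmle` — targeted minimum loss-based estimation: iteratively
  fluctuates the outcome regression (logistic submodel with the clever
  covariate) and, jointly, the exposure mechanism (one-parameter exponential
  tilt), until the empirical mean of the efficient influence function is
  negligible; the estimate is the plug-in at the targeted fits, so it always
  respects the parameter bounds.
* :func:`ee_estimator` — the estimating-equation estimator: the closed-form
  zero of the efficient-influence-function estimating equation at the
  initial nuisance fits.  May land outside the parameter space, in which
  case it is returned with a flag.
* :func:`gcomp_ipmw` — a G-computation / inverse-probability-of-missingness
  hybrid with stepwise-logistic nuisances, representing common practice; it
  is consistent only when both of its parametric models are right.
* :func:`unadjusted` — Gcomp/IPMW with an intercept-only adjustment set.

Inference for all estimators is influence-curve based: se = sd(D)/sqrt(n),
Wald 95% CI, two-sided normal p-value for psi = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm

from .data import CrossSection
from .superlearner import _GLMLearner, _StepwiseLearner
from .vim import (
    EIFValue,
    NuisanceSet,
    ShiftSpec,
    _as_matrix,
    _check_binary_bound,
    binary_means,
    eif_values,
)

__all__ = ["VIMEstimate", "tmle", "ee_estimator", "gcomp_ipmw", "unadjusted",
           "wald_inference"]

_PCLIP = 1e-6


@dataclass
class VIMEstimate:
    psi: float
    se: float
    p_value: float
    ci: tuple[float, float]
    estimator: str
    spec: ShiftSpec
    meta: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def wald_inference(psi: float, eif, alpha: float = 0.05):
    """Influence-curve Wald inference: (se, ci, p_value)."""
    d = eif.d if isinstance(eif, EIFValue) else np.asarray(eif, float)
    n = len(d)
    if n < 2:
        raise ValueError("need n >= 2 for influence-curve inference")
    se = float(np.std(d, ddof=1) / np.sqrt(n))
    if se == 0.0:
        warnings.warn("degenerate influence curve: zero variance")
        return 0.0, (psi, psi), float("nan")
    z = norm.ppf(1 - alpha / 2)
    ci = (psi - z * se, psi + z * se)
    p = float(2 * norm.sf(abs(psi) / se))
    return se, ci, p


def _finish(psi, d, estimator, spec, meta, diagnostics, alpha):
    se, ci, p = wald_inference(psi, d, alpha)
    return VIMEstimate(float(psi), se, p, ci, estimator, spec,
                       dict(meta or {}), diagnostics)


# ---------------------------------------------------------------------------
# EE


def ee_estimator(
    cs: CrossSection,
    nuis: NuisanceSet,
    spec: ShiftSpec,
    alpha: float = 0.05,
    n_grid: int = 200,
) -> VIMEstimate:
    """Closed-form solution of the EIF estimating equation."""
    at_zero = eif_values(nuis, cs, spec, psi=0.0, n_grid=n_grid)
    psi = float(np.mean(at_zero.d))
    eif = EIFValue(d=at_zero.d - psi, plug_in=at_zero.plug_in, psi=psi)
    diags = {"out_of_range": bool(abs(psi) > 1.0), "plug_in": at_zero.plug_in}
    if diags["out_of_range"]:
        warnings.warn("EE estimate outside the parameter space [-1, 1]")
    return _finish(psi, eif.d, "EE", spec, cs.meta, diags, alpha)


# ---------------------------------------------------------------------------
# TMLE helpers


def _fit_scalar_logistic(loglik, bound: float):
    """Maximize a 1-parameter log-likelihood over [-bound, bound]."""
    res = minimize_scalar(lambda e: -loglik(e), bounds=(-bound, bound),
                          method="bounded", options={"xatol": 1e-10})
    return float(res.x)


def _bern_ll(y, lp):
    p = np.clip(expit(lp), _PCLIP, 1 - _PCLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _tmle_continuous(cs, nuis, spec, max_iter, n_grid, alpha, iterative):
    Wm = _as_matrix(cs.W)
    n = cs.n
    phi = nuis.phi_of(Wm)
    c = cs.C.astype(float)
    y = cs.Y.astype(float)
    obs = c > 0
    delta = spec.delta
    floor = getattr(nuis.g, "floor", 1e-3)
    hmax = 1.0 / floor

    nodes, masses = nuis.g.grid_masses(Wm, n_grid)
    M = len(nodes)
    a_fill = np.where(obs, cs.A, 0.5)

    def node_idx(a):
        return np.clip(np.floor(np.asarray(a, float) * M).astype(int), 0, M - 1)

    def pdf_state(a):
        a = np.asarray(a, float)
        out = masses[np.arange(n), node_idx(a)] * M
        out[(a < 0) | (a > 1)] = 0.0
        return out

    # logit-scale Qbar state at every evaluation point ever needed
    lq_obs = logit(np.clip(nuis.qbar.predict(a_fill, Wm), _PCLIP, 1 - _PCLIP))
    lq_shift = logit(np.clip(nuis.qbar.predict(a_fill + delta, Wm), _PCLIP, 1 - _PCLIP))
    lq_grid = logit(
        np.clip(nuis.qbar.predict_grid(nodes + delta, Wm), _PCLIP, 1 - _PCLIP)
    )

    eps_hist, eta_hist = [], []
    converged = False
    mean_d = np.inf
    for it in range(max_iter):
        r_obs = pdf_state(a_fill - delta) / np.maximum(pdf_state(a_fill), floor)
        H_obs = np.clip(r_obs / phi, 0.0, hmax)
        # covariate at the shifted evaluation points x = a + delta, nodes + delta
        H_shift = np.clip(
            pdf_state(a_fill) / np.maximum(pdf_state(a_fill + delta), floor) / phi,
            0.0, hmax,
        )
        H_grid = np.empty((n, M))
        for mcol, av in enumerate(nodes):
            H_grid[:, mcol] = np.clip(
                pdf_state(np.full(n, av))
                / np.maximum(pdf_state(np.full(n, av + delta)), floor) / phi,
                0.0, hmax,
            )

        eps = _fit_scalar_logistic(
            lambda e: _bern_ll(y[obs], lq_obs[obs] + e * H_obs[obs]), 1.0
        )
        lq_obs = lq_obs + eps * H_obs
        lq_shift = lq_shift + eps * H_shift
        lq_grid = lq_grid + eps * H_grid
        eps_hist.append(eps)

        q_grid = expit(lq_grid)
        m = (masses * q_grid).sum(axis=1)
        q_at_a = np.where(obs, expit(lq_shift), 0.0)
        wts = c / phi

        def tilt_ll(eta):
            Z = (masses * np.exp(eta * (q_grid - m[:, None]))).sum(axis=1)
            return float(np.sum(wts * (eta * (q_at_a - m) - np.log(Z))))

        eta = _fit_scalar_logistic(tilt_ll, 20.0)
        tiltw = np.exp(eta * (q_grid - m[:, None]))
        masses = masses * tiltw
        masses = masses / masses.sum(axis=1, keepdims=True)
        eta_hist.append(eta)

        m = (masses * q_grid).sum(axis=1)
        psi = float(np.mean(m) - np.mean(y))
        r_obs = pdf_state(a_fill - delta) / np.maximum(pdf_state(a_fill), floor)
        d = (
            wts * (np.clip(r_obs, 0, hmax) * (y - expit(lq_obs))
                   + expit(lq_shift) - m)
            + m - y - psi
        )
        mean_d = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(n))
        if abs(mean_d) < max(se / max(np.log(n), 1.0), 1e-10) or not iterative:
            converged = True
            break
    if not converged:
        warnings.warn("TMLE did not converge within max_iter; returning last iterate")
    diags = {
        "n_iter": len(eps_hist),
        "converged": converged,
        "mean_eif": mean_d,
        "eps": eps_hist,
        "eta": eta_hist,
        "intervened_mean": float(np.mean(m)),
    }
    return _finish(psi, d - mean_d, "TMLE", spec, cs.meta, diags, alpha)


def _tmle_binary(cs, nuis, spec, max_iter, alpha, iterative):
    Wm = _as_matrix(cs.W)
    n = cs.n
    phi = nuis.phi_of(Wm)
    c = cs.C.astype(float)
    y = cs.Y.astype(float)
    obs = c > 0
    delta = spec.delta
    floor = 1e-3

    g1, qb1, qb0, _, _ = binary_means(nuis, cs.W, delta)
    _check_binary_bound(g1, delta)
    lq1 = logit(np.clip(qb1, _PCLIP, 1 - _PCLIP))
    lq0 = logit(np.clip(qb0, _PCLIP, 1 - _PCLIP))
    lg1 = logit(np.clip(g1, _PCLIP, 1 - _PCLIP))
    a_fill = np.where(obs, cs.A, 0.0)
    wts = c / phi

    eps_hist, eta_hist = [], []
    converged = False
    for it in range(max_iter):
        g1 = np.clip(expit(lg1), _PCLIP, 1.0 - delta - 1e-9)
        H1 = (g1 + delta) / np.maximum(g1, floor) / phi
        H0 = (1.0 - g1 - delta) / np.maximum(1.0 - g1, floor) / phi
        H_obs = np.where(a_fill > 0.5, H1, H0)
        eps = _fit_scalar_logistic(
            lambda e: _bern_ll(y[obs], np.where(a_fill[obs] > 0.5, lq1[obs], lq0[obs])
                               + e * H_obs[obs]), 1.0
        )
        lq1 = lq1 + eps * H1
        lq0 = lq0 + eps * H0
        eps_hist.append(eps)

        qb1, qb0 = expit(lq1), expit(lq0)
        dq = qb1 - qb0
        eta = _fit_scalar_logistic(
            lambda e: float(np.sum(
                wts[obs] * (
                    a_fill[obs] * np.log(np.clip(expit(lg1[obs] + e * dq[obs]),
                                                 _PCLIP, 1 - _PCLIP))
                    + (1 - a_fill[obs]) * np.log(np.clip(
                        1 - expit(lg1[obs] + e * dq[obs]), _PCLIP, 1 - _PCLIP))
                )
            )), 5.0
        )
        lg1 = lg1 + eta * dq
        eta_hist.append(eta)

        g1 = np.clip(expit(lg1), _PCLIP, 1.0 - delta - 1e-9)
        m0 = g1 * qb1 + (1 - g1) * qb0
        mb = m0 + delta * dq
        psi = float(np.mean(mb) - np.mean(y))
        gstar_obs = np.where(a_fill > 0.5, g1 + delta, 1.0 - g1 - delta)
        gobs = np.where(a_fill > 0.5, g1, 1.0 - g1)
        r = gstar_obs / np.maximum(gobs, floor)
        q_obs = np.where(a_fill > 0.5, qb1, qb0)
        d = wts * (r * (y - q_obs) + q_obs - m0) + mb - y - psi
        mean_d = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(n))
        if abs(mean_d) < max(se / max(np.log(n), 1.0), 1e-10) or not iterative:
            converged = True
            break
    if not converged:
        warnings.warn("TMLE did not converge within max_iter; returning last iterate")
    diags = {
        "n_iter": len(eps_hist),
        "converged": converged,
        "mean_eif": mean_d,
        "eps": eps_hist,
        "eta": eta_hist,
        "intervened_mean": float(np.mean(mb)),
    }
    return _finish(psi, d - mean_d, "TMLE", spec, cs.meta, diags, alpha)


def tmle(
    cs: CrossSection,
    nuis: NuisanceSet,
    spec: ShiftSpec,
    max_iter: int = 20,
    alpha: float = 0.05,
    n_grid: int = 200,
    iterative: bool = True,
) -> VIMEstimate:
    """Targeted minimum loss-based estimate of the VIM.

    Per iteration the outcome regression is fluctuated along a logistic
    submodel with the clever covariate (maximum-likelihood epsilon), the
    exposure mechanism along a one-parameter exponential tilt, and the
    intervened mean is recomputed by quadrature.  Stops when
    |mean EIF| < se / log(n) (or after one pass with ``iterative=False``).
    The reported influence curve is recentered so the stored se/CI/p follow
    the usual Wald construction.
    """
    if spec.kind == "continuous":
        return _tmle_continuous(cs, nuis, spec, max_iter, n_grid, alpha, iterative)
    return _tmle_binary(cs, nuis, spec, max_iter, alpha, iterative)


# ---------------------------------------------------------------------------
# Gcomp/IPMW and unadjusted


def _stepwise_or_glm(X, y, use_stepwise):
    if X.shape[1] == 0:
        mean = float(np.mean(y))
        class _Const:
            def predict_proba1(self, Xn):
                return np.full(len(Xn), mean)
        return _Const()
    if use_stepwise:
        try:
            return _StepwiseLearner().fit(X, y)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"stepwise fit failed ({exc}); using main-terms logistic")
    return _GLMLearner().fit(X, y)


def gcomp_ipmw(
    cs: CrossSection,
    spec: ShiftSpec,
    alpha: float = 0.05,
    stepwise: bool = True,
    nuisances: NuisanceSet | None = None,
    _intercept_only: bool = False,
) -> VIMEstimate:
    """G-computation / IPMW estimator with stepwise-logistic nuisances.

    Continuous:  psi = mean_i[ (C_i/phi_n(W_i)) Qbar_n(A_i+delta, 1, W_i) - Y_i ].
    Binary:      psi = mean_i[ (C_i/phi_n(W_i)) (Qbar_n(A_i,1,W_i)
                              + delta (Qbar_n(1,1,W_i) - Qbar_n(0,1,W_i))) - Y_i ].

    The standard error is the naive plug-in influence curve (nuisance
    estimation ignored), as in common practice.  Passing ``nuisances``
    substitutes externally fitted (Qbar, phi) for the internal stepwise fits.
    """
    Wm = _as_matrix(cs.W)
    if _intercept_only:
        Wm = np.empty((cs.n, 0))
    c = cs.C.astype(float)
    y = cs.Y.astype(float)
    obs = c > 0

    if nuisances is not None:
        phi = nuisances.phi_of(_as_matrix(cs.W))

        def qhat(a):
            return nuisances.qbar.predict(a, _as_matrix(cs.W))
    else:
        if obs.all():
            phi = np.ones(cs.n)
        else:
            phi_model = _stepwise_or_glm(Wm, c, stepwise)
            phi = np.clip(phi_model.predict_proba1(Wm), 1e-6, 1.0)

        qmodel = _stepwise_or_glm(
            np.column_stack([cs.A[obs], Wm[obs]]), y[obs], stepwise
        )

        def qhat(a):
            a = np.full(cs.n, a) if np.ndim(a) == 0 else np.asarray(a, float)
            return qmodel.predict_proba1(np.column_stack([a, Wm]))

    a_fill = np.where(obs, cs.A, 0.0)
    if spec.kind == "continuous":
        contrib = (c / phi) * qhat(a_fill + spec.delta)
    else:
        contrib = (c / phi) * (qhat(a_fill) + spec.delta * (qhat(1.0) - qhat(0.0)))
    summand = contrib - y
    psi = float(np.mean(summand))
    name = "Unadjusted" if _intercept_only else "GcompIPMW"
    return _finish(psi, summand - psi, name, spec, cs.meta, {}, alpha)


def unadjusted(cs: CrossSection, spec: ShiftSpec, alpha: float = 0.05) -> VIMEstimate:
    """Gcomp/IPMW with only the intercept term in the adjustment set."""
    return gcomp_ipmw(cs, spec, alpha=alpha, stepwise=False, _intercept_only=True)
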
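"""Target parameters, clever covariates, and efficient influence functions.

Two variable-importance parameters are defined on a cross-section
(W, C, A, Y), both of the form E(Y^I) - E(Y) for a stochastic intervention
on the exposure-generating mechanism:

* continuous exposure, shift intervention: every draw of A is moved up by
  delta, and the exposure is always observed under the intervention;
  identification gives

      Psi_c = E_W  E_g[ Qbar(A + delta, 1, W) | C = 1, W ]  -  E(Y),

  with Qbar(a, c, w) = E(Y | A=a, C=c, W=w), g the conditional density of A
  given (C=1, W), and phi(1|w) = P(C=1 | W=w).

* binary exposure, probability shift: P(A=1) is raised by delta (requiring
  0 < delta < inf_w g(0|1,w));

      Psi_b = E_W[ sum_a g*(a|W) Qbar(a, 1, W) ] - E(Y),
      g*(1|w) = g(1|1,w) + delta,   g*(0|w) = g(0|1,w) - delta.

The efficient influence function used throughout (derived from the
likelihood factorization Q_W x phi x g x Q, and validated by the mean-zero /
double-robustness property suite) is, writing m(w) for the intervened
conditional mean and r for the relevant density ratio,

    D(O) = (C/phi(1|W)) [ r(A,W) (Y - Qbar(A,1,W)) + s(A,W) - m_g(W) ]
           + m(W) - Y - psi,

where for the continuous parameter r(a,w) = g(a-delta|1,w)/g(a|1,w),
s(a,w) = Qbar(a+delta,1,w) and m_g = m; for the binary parameter
r(a,w) = g*(a|w)/g(a|1,w), s(a,w) = Qbar(a,1,w) and m_g is the *no-shift*
mean  sum_a g(a|1,w) Qbar(a,1,w).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data import CrossSection
from .density import density_fit
from .superlearner import DEFAULT_LIBRARY, EnsembleFit, sl_fit, sl_predict

__all__ = [
    "ShiftSpec",
    "NuisanceSet",
    "EIFValue",
    "PositivityBoundError",
    "PositivityReport",
    "FittedOutcomeRegression",
    "TrueOutcomeRegression",
    "FittedBinaryExposure",
    "TrueBinaryExposure",
    "ExactConditionalDensity",
    "fit_nuisances",
    "plug_in_psi_c",
    "plug_in_psi_b",
    "shift_mean_continuous",
    "binary_means",
    "clever_covariate",
    "eif_values",
    "positivity_check",
]


class PositivityBoundError(ValueError):
    """delta violates the binary positivity bound delta < min_w g(0|1,w)."""


@dataclass(frozen=True)
class ShiftSpec:
    """Intervention magnitude and exposure kind."""

    delta: float
    kind: str  # "continuous" | "binary"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown exposure kind {self.kind!r}")


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(W, dtype=float))


# ---------------------------------------------------------------------------
# nuisance wrappers


class FittedOutcomeRegression:
    """Outcome regression Qbar(a, 1, w) backed by a stacked ensemble fit.

    The ensemble was trained on rows with C = 1 and features [A, W]; setting
    the exposure column evaluates the regression at arbitrary exposure
    levels, including extrapolation beyond the observed support (no clipping
    of the exposure argument).
    """

    def __init__(self, fit: EnsembleFit):
        self.fit = fit

    def predict(self, a, W) -> np.ndarray:
        Wm = _as_matrix(W)
        a = np.asarray(a, float)
        if a.ndim == 0:
            a = np.full(len(Wm), float(a))
        return sl_predict(self.fit, np.column_stack([a, Wm]))

    def predict_grid(self, avals, W) -> np.ndarray:
        return _predict_grid(self, avals, W)


class TrueOutcomeRegression:
    """Closed-form Qbar(a, 1, w) for scenarios with known truth."""

    def __init__(self, fn: Callable[[np.ndarray, np.ndarray], np.ndarray]):
        self.fn = fn

    def predict(self, a, W) -> np.ndarray:
        Wm = _as_matrix(W)
        a = np.asarray(a, float)
        if a.ndim == 0:
            a = np.full(len(Wm), float(a))
        return np.asarray(self.fn(a, Wm), float)

    def predict_grid(self, avals, W) -> np.ndarray:
        return _predict_grid(self, avals, W)


def _predict_grid(qbar, avals, W, chunk: int = 2_000_000) -> np.ndarray:
    """Evaluate qbar at every (grid value, covariate row) pair: (n, M) array."""
    Wm = _as_matrix(W)
    n, M = len(Wm), len(avals)
    out = np.empty((n, M))
    per = max(1, chunk // max(n, 1))
    for start in range(0, M, per):
        sub = np.asarray(avals[start : start + per], float)
        big_a = np.repeat(sub, n)
        big_w = np.tile(Wm, (len(sub), 1))
        out[:, start : start + len(sub)] = (
            qbar.predict(big_a, big_w).reshape(len(sub), n).T
        )
    return out


class FittedBinaryExposure:
    """g(1 | C=1, w) backed by a stacked ensemble fit."""

    def __init__(self, fit: EnsembleFit):
        self.fit = fit

    def prob1(self, W) -> np.ndarray:
        return sl_predict(self.fit, _as_matrix(W))


class TrueBinaryExposure:
    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self.fn = fn

    def prob1(self, W) -> np.ndarray:
        return np.clip(np.asarray(self.fn(_as_matrix(W)), float), 1e-6, 1 - 1e-6)


class ExactConditionalDensity:
    """Closed-form conditional density with the histogram-density interface."""

    def __init__(self, pdf_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
                 floor: float = 1e-3, n_grid: int = 400):
        self.pdf_fn = pdf_fn
        self.floor = floor
        self.n_grid = n_grid

    def pdf(self, a, W) -> np.ndarray:
        Wm = _as_matrix(W)
        a = np.asarray(a, float)
        if a.ndim == 0:
            a = np.full(len(Wm), float(a))
        out = np.asarray(self.pdf_fn(a, Wm), float).copy()
        out[(a < 0) | (a > 1)] = 0.0
        return out

    def pdf_floored(self, a, W) -> np.ndarray:
        return np.maximum(self.pdf(a, W), self.floor)

    def grid_masses(self, W, n_grid: int | None = None):
        Wm = _as_matrix(W)
        M = n_grid or self.n_grid
        nodes = (np.arange(M) + 0.5) / M
        masses = np.empty((len(Wm), M))
        for mcol, av in enumerate(nodes):
            masses[:, mcol] = self.pdf(av, Wm)
        tot = masses.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return nodes, masses / tot


@dataclass
class NuisanceSet:
    """Fitted nuisances for one cross-section.

    ``qbar`` maps (a, W) -> E(Y | A=a, C=1, W); ``g`` is a conditional
    density (continuous) or a binary-exposure model (binary); ``phi`` maps
    W -> P(C=1 | W).  The empirical distribution of W (the sample itself)
    plays the role of Q_W.
    """

    qbar: object
    g: object
    phi: Callable[[np.ndarray], np.ndarray]
    meta: dict = field(default_factory=dict)

    def phi_of(self, W) -> np.ndarray:
        return np.clip(np.asarray(self.phi(_as_matrix(W)), float), 1e-6, 1.0)


@dataclass
class EIFValue:
    """Per-observation influence contributions at a candidate psi."""

    d: np.ndarray
    plug_in: float
    psi: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.d))

    @property
    def se(self) -> float:
        return float(np.std(self.d, ddof=1) / np.sqrt(len(self.d)))


# ---------------------------------------------------------------------------
# nuisance fitting


def _constant_phi(value: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda Wm: np.full(len(Wm), value)


def fit_nuisances(
    cs: CrossSection,
    library=DEFAULT_LIBRARY,
    V: int = 10,
    seed: int = 0,
    density_grid=None,
    density_V: int = 5,
    density_floor: float = 1e-3,
    hazard: str = "logistic",
) -> NuisanceSet:
    """Fit (Qbar, g, phi) for one cross-section with stacked learners.

    Qbar and the binary-exposure g are fit on rows with observed exposure;
    phi is fit on all rows (constant 1 when nothing is missing).
    """
    W = _as_matrix(cs.W)
    obs = cs.C.astype(bool)
    if obs.all():
        phi = _constant_phi(1.0)
    else:
        phi_fit = sl_fit(W, cs.C.astype(float), library=library, V=V, seed=seed + 1)
        phi = lambda Wm, _f=phi_fit: sl_predict(_f, Wm)  # noqa: E731
    Xq = np.column_stack([cs.A[obs], W[obs]])
    qbar = FittedOutcomeRegression(
        sl_fit(Xq, cs.Y[obs].astype(float), library=library, V=V, seed=seed + 2)
    )
    if cs.exposure_kind == "continuous":
        from .density import DEFAULT_GRID

        g = density_fit(
            cs.A[obs], W[obs], candidates=density_grid or DEFAULT_GRID,
            V=density_V, seed=seed + 3, hazard=hazard, floor=density_floor,
        )
    else:
        g = FittedBinaryExposure(
            sl_fit(W[obs], cs.A[obs].astype(float), library=library, V=V,
                   seed=seed + 3)
        )
    return NuisanceSet(qbar=qbar, g=g, phi=phi)


# ---------------------------------------------------------------------------
# parameter values


def shift_mean_continuous(
    nuis: NuisanceSet, W, delta: float, n_grid: int = 200,
    row_chunk: int = 20_000,
) -> np.ndarray:
    """m(w) = integral of Qbar(a + delta, 1, w) g(a | 1, w) da, by per-node quadrature.

    Rows are processed in chunks so the (rows x grid) mass matrix never
    exceeds a few tens of MB regardless of sample size.
    """
    Wm = _as_matrix(W)
    m = np.empty(len(Wm))
    for start in range(0, len(Wm), row_chunk):
        Wc = Wm[start : start + row_chunk]
        nodes, masses = nuis.g.grid_masses(Wc, n_grid)
        acc = np.zeros(len(Wc))
        for mcol, a in enumerate(nodes):
            acc += masses[:, mcol] * nuis.qbar.predict(a + delta, Wc)
        m[start : start + len(Wc)] = acc
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite quadrature in shifted mean")
    return m


def plug_in_psi_c(
    nuis: NuisanceSet, cs: CrossSection, spec: ShiftSpec, n_grid: int = 200
) -> float:
    """Plug-in value of the continuous-shift parameter at the given nuisances."""
    m = shift_mean_continuous(nuis, cs.W, spec.delta, n_grid)
    return float(np.mean(m) - np.mean(cs.Y))


def binary_means(nuis: NuisanceSet, W, delta: float):
    """Return (g1, qb1, qb0, m0, mb) for the binary parameter.

    m0 is the no-shift mean sum_a g(a|1,w) Qbar(a,1,w); mb adds the
    delta-contrast term and is the intervened mean.
    """
    Wm = _as_matrix(W)
    g1 = nuis.g.prob1(Wm)
    qb1 = nuis.qbar.predict(1.0, Wm)
    qb0 = nuis.qbar.predict(0.0, Wm)
    m0 = g1 * qb1 + (1.0 - g1) * qb0
    mb = m0 + delta * (qb1 - qb0)
    return g1, qb1, qb0, m0, mb


def _check_binary_bound(g1: np.ndarray, delta: float) -> None:
    bound = float(np.min(1.0 - g1))
    if delta >= bound:
        raise PositivityBoundError(
            f"delta = {delta} violates delta < min_w g(0|1,w) = {bound:.4g}"
        )


def plug_in_psi_b(nuis: NuisanceSet, cs: CrossSection, spec: ShiftSpec) -> float:
    """Plug-in value of the binary probability-shift parameter."""
    g1, _, _, _, mb = binary_means(nuis, cs.W, spec.delta)
    _check_binary_bound(g1, spec.delta)
    return float(np.mean(mb) - np.mean(cs.Y))


# ---------------------------------------------------------------------------
# clever covariate and EIF


def _ratio_continuous(nuis: NuisanceSet, a: np.ndarray, W, delta: float) -> np.ndarray:
    """g(a - delta | 1, w) / g(a | 1, w), floored denominator, 0 below support."""
    num = nuis.g.pdf(a - delta, W)
    den = nuis.g.pdf_floored(a, W)
    return num / den


def clever_covariate(nuis: NuisanceSet, spec: ShiftSpec, a, c, W) -> np.ndarray:
    """Targeting covariate H(a, c, w); zero where c = 0."""
    Wm = _as_matrix(W)
    c = np.asarray(c, float)
    a = np.asarray(a, float)
    if a.ndim == 0:
        a = np.full(len(Wm), float(a))
    phi = nuis.phi_of(Wm)
    a_fill = np.where(c > 0, a, 0.5)
    if spec.kind == "continuous":
        core = _ratio_continuous(nuis, a_fill, Wm, spec.delta)
    else:
        g1 = nuis.g.prob1(Wm)
        _check_binary_bound(g1, spec.delta)
        gstar = np.where(a_fill > 0.5, g1 + spec.delta, (1.0 - g1) - spec.delta)
        gobs = np.where(a_fill > 0.5, g1, 1.0 - g1)
        core = gstar / np.clip(gobs, nuis.g.floor if hasattr(nuis.g, "floor") else 1e-3, None)
    return np.where(c > 0, core / phi, 0.0)


def eif_values(
    nuis: NuisanceSet,
    cs: CrossSection,
    spec: ShiftSpec,
    psi: float,
    n_grid: int = 200,
) -> EIFValue:
    """Efficient-influence-function contributions D(O_i) at a candidate psi.

    Assembled so that ``mean(d) == psi_EE - psi``: the estimating-equation
    estimate is the unique zero, and at the plug-in the mean equals the
    one-step correction.
    """
    Wm = _as_matrix(cs.W)
    phi = nuis.phi_of(Wm)
    c = cs.C.astype(float)
    y = cs.Y.astype(float)
    a_fill = np.where(c > 0, cs.A, 0.5)
    q_obs = nuis.qbar.predict(a_fill, Wm)
    if spec.kind == "continuous":
        r = _ratio_continuous(nuis, a_fill, Wm, spec.delta)
        s = nuis.qbar.predict(a_fill + spec.delta, Wm)
        m = shift_mean_continuous(nuis, cs.W, spec.delta, n_grid)
        m_g = m
        plug_in = float(np.mean(m) - np.mean(y))
    else:
        g1, _, _, m0, mb = binary_means(nuis, cs.W, spec.delta)
        _check_binary_bound(g1, spec.delta)
        r = clever_covariate(nuis, spec, a_fill, np.ones_like(c), Wm) * phi
        s = q_obs
        m, m_g = mb, m0
        plug_in = float(np.mean(mb) - np.mean(y))
    d = (
        (c / phi) * (r * (y - q_obs) + s - m_g)
        + m
        - y
        - psi
    )
    return EIFValue(d=d, plug_in=plug_in, psi=float(psi))


# ---------------------------------------------------------------------------
# positivity diagnostics


@dataclass
class PositivityReport:
    phi_quantiles: dict
    g_obs_quantiles: dict
    g_shift_quantiles: dict
    n_flagged: int
    flags: np.ndarray
    floor: float

    def summary(self) -> str:
        return (
            f"positivity: {self.n_flagged} flagged below floor {self.floor}; "
            f"min phi = {self.phi_quantiles['min']:.4g}, "
            f"min g(obs) = {self.g_obs_quantiles['min']:.4g}"
        )


def _quants(x: np.ndarray) -> dict:
    qs = np.quantile(x, [0.0, 0.01, 0.05, 0.5])
    return {"min": float(qs[0]), "q01": float(qs[1]), "q05": float(qs[2]),
            "median": float(qs[3])}


def positivity_check(
    nuis: NuisanceSet, cs: CrossSection, spec: ShiftSpec, floor: float = 1e-3
) -> PositivityReport:
    """Report the small-denominator tail of phi and g and flag observations."""
    Wm = _as_matrix(cs.W)
    phi = nuis.phi_of(Wm)
    obs = cs.C.astype(bool)
    a_fill = np.where(obs, cs.A, 0.5)
    if spec.kind == "continuous":
        g_obs = nuis.g.pdf(a_fill, Wm)
        g_shift = nuis.g.pdf(np.clip(a_fill + spec.delta, 0.0, 1.0), Wm)
    else:
        g1 = nuis.g.prob1(Wm)
        g_obs = np.where(a_fill > 0.5, g1, 1.0 - g1)
        g_shift = 1.0 - g1  # the bound-relevant arm under the probability shift
    flags = (phi < floor) | (obs & (g_obs < floor))
    return PositivityReport(
        phi_quantiles=_quants(phi),
        g_obs_quantiles=_quants(g_obs[obs]) if obs.any() else _quants(g_obs),
        g_shift_quantiles=_quants(g_shift),
        n_flagged=int(flags.sum()),
        flags=flags,
        floor=floor,
    )
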
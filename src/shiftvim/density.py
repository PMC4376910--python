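"""Piecewise-constant conditional density estimation for continuous exposures.

The exposure mechanism g(a | C=1, W) of a continuous exposure on [0,1] is
estimated by a stack of histogram estimators.  Each candidate partitions
[0,1] into bins (equal-width or equal-frequency placement) and models bin
membership sequentially, hazard-style: for bin b,
P(A in bin_b | A not in earlier bins, W) is a binary regression on W, and the
bin probabilities are the product-of-hazards.  Within a bin the density is
constant (bin probability / bin width).  Candidates over a grid of
(number of bins, placement) are combined with convex weights chosen to
maximize the cross-validated log-density, mirroring the stacking used for
binary regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .superlearner import simplex_weights, sl_fit, sl_predict

__all__ = ["HistogramDensity", "density_fit", "density_eval", "DensityFitError"]

DEFAULT_GRID = tuple(
    (b, p) for b in (2, 5, 10, 20) for p in ("equal_width", "equal_frequency")
)


class DensityFitError(RuntimeError):
    pass


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(dtype=float)
    return np.asarray(W, dtype=float)


class _ConstHazard:
    def __init__(self, p: float):
        self.p = p

    def predict_proba1(self, W) -> np.ndarray:
        return np.full(len(W), self.p)


class _HistogramCandidate:
    """One histogram density: fixed bin edges + per-bin hazard regressions."""

    def __init__(self, n_bins: int, placement: str, hazard: str = "logistic",
                 sl_opts: dict | None = None):
        if placement not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown placement {placement!r}")
        self.n_bins = n_bins
        self.placement = placement
        self.hazard = hazard
        self.sl_opts = sl_opts or {}

    def _edges(self, A: np.ndarray) -> np.ndarray:
        if self.placement == "equal_width":
            edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        else:
            edges = np.quantile(A, np.linspace(0.0, 1.0, self.n_bins + 1))
            edges[0], edges[-1] = 0.0, 1.0
            edges = np.unique(edges)
        if len(edges) < 3 and self.n_bins > 1:
            raise DensityFitError("degenerate bin edges")
        return edges

    def fit(self, A: np.ndarray, W: np.ndarray):
        if len(A) < self.n_bins:
            raise DensityFitError("fewer observations than bins")
        self.edges_ = self._edges(A)
        B = len(self.edges_) - 1
        idx = np.clip(np.searchsorted(self.edges_, A, side="right") - 1, 0, B - 1)
        self.models_ = []
        for b in range(B - 1):
            mask = idx >= b
            yb = (idx[mask] == b).astype(float)
            nb = mask.sum()
            if len(np.unique(yb)) < 2 or nb < 10:
                self.models_.append(_ConstHazard((yb.sum() + 0.5) / (nb + 1.0)))
                continue
            if self.hazard == "sl":
                fit = sl_fit(W[mask], yb, **self.sl_opts)
                self.models_.append(("sl", fit))
            else:
                try:
                    m = LogisticRegression(C=1e4, max_iter=1000).fit(W[mask], yb)
                    self.models_.append(m)
                except Exception:  # pragma: no cover - separation fallback
                    self.models_.append(_ConstHazard((yb.sum() + 0.5) / (nb + 1.0)))
        return self

    def bin_probs(self, W: np.ndarray) -> np.ndarray:
        """(n, B) matrix of P(A in bin_b | w); rows sum to 1 exactly."""
        n = len(W)
        B = len(self.edges_) - 1
        probs = np.empty((n, B))
        surv = np.ones(n)
        for b, model in enumerate(self.models_):
            if isinstance(model, tuple):
                h = sl_predict(model[1], W)
            else:
                h = np.clip(model.predict_proba1(W) if isinstance(model, _ConstHazard)
                            else model.predict_proba(W)[:, 1], 1e-6, 1 - 1e-6)
            probs[:, b] = surv * h
            surv = surv * (1.0 - h)
        probs[:, B - 1] = surv
        return probs

    def pdf(self, a: np.ndarray, W: np.ndarray) -> np.ndarray:
        a = np.atleast_1d(np.asarray(a, float))
        probs = self.bin_probs(W)
        widths = np.diff(self.edges_)
        B = len(widths)
        idx = np.clip(np.searchsorted(self.edges_, a, side="right") - 1, 0, B - 1)
        out = probs[np.arange(len(a)), idx] / widths[idx]
        out[(a < 0) | (a > 1)] = 0.0
        return out


@dataclass
class HistogramDensity:
    """Convex stack of fitted histogram candidates."""

    candidates: list[_HistogramCandidate]
    weights: np.ndarray
    cv_loglik: np.ndarray  # per-candidate CV log-density (NaN where dropped)
    floor: float = 1e-3

    def pdf(self, a, W) -> np.ndarray:
        """Mixture density at ``a`` (scalar or row-aligned vector); 0 outside [0,1]."""
        Wm = _as_matrix(W)
        a = np.asarray(a, float)
        scalar = a.ndim == 0
        a = np.full(len(Wm), float(a)) if scalar else a
        out = np.zeros(len(Wm))
        for w, c in zip(self.weights, self.candidates):
            if w > 0:
                out += w * c.pdf(a, Wm)
        return out

    def pdf_floored(self, a, W) -> np.ndarray:
        """Density with the positivity floor applied (ratio denominators)."""
        return np.maximum(self.pdf(a, W), self.floor)

    def grid_masses(self, W, n_grid: int = 200) -> tuple[np.ndarray, np.ndarray]:
        """Discretize g(.|w) on a uniform midpoint grid over [0,1].

        Returns ``(nodes, masses)`` with ``nodes`` of length ``n_grid`` and
        ``masses[i]`` summing to 1; used for quadrature of shifted-outcome
        means and for the targeting tilt.
        """
        Wm = _as_matrix(W)
        nodes = (np.arange(n_grid) + 0.5) / n_grid
        masses = np.empty((len(Wm), n_grid))
        for mcol, a in enumerate(nodes):
            masses[:, mcol] = self.pdf(a, Wm)
        tot = masses.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return nodes, masses / tot

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_bins": [c.n_bins for c in self.candidates],
                "placement": [c.placement for c in self.candidates],
                "cv_loglik": self.cv_loglik,
                "weight": self.weights,
            }
        )


def density_fit(
    A,
    W,
    candidates=DEFAULT_GRID,
    V: int = 5,
    seed: int = 0,
    hazard: str = "logistic",
    floor: float = 1e-3,
    sl_opts: dict | None = None,
) -> HistogramDensity:
    """Fit the stacked histogram density of A | W on rows with observed A.

    Stacking weights maximize the V-fold cross-validated log-density of the
    mixture.  A candidate that cannot be fit (degenerate edges, too few
    observations) is dropped with a warning; if all candidates drop, a
    :class:`DensityFitError` is raised.
    """
    A = np.asarray(A, float)
    W = _as_matrix(W)
    if np.any((A <= 0) | (A >= 1)):
        raise ValueError("continuous exposure must lie in (0,1)")
    n = len(A)
    C = len(candidates)
    kf = KFold(n_splits=max(2, min(V, n)), shuffle=True, random_state=seed)
    F = np.full((n, C), np.nan)  # out-of-fold density evaluations
    alive = np.ones(C, dtype=bool)
    for tr, te in kf.split(A):
        for ci, (b, place) in enumerate(candidates):
            if not alive[ci]:
                continue
            try:
                cand = _HistogramCandidate(b, place, hazard, sl_opts).fit(A[tr], W[tr])
                F[te, ci] = cand.pdf(A[te], W[te])
            except Exception as exc:  # noqa: BLE001 - candidate isolation
                alive[ci] = False
                warnings.warn(f"density candidate ({b},{place}) dropped: {exc}")
    if not alive.any():
        raise DensityFitError("all histogram candidates failed")

    def neg_loglik(w: np.ndarray) -> float:
        mix = F[:, alive] @ w[alive]
        return -float(np.mean(np.log(np.clip(mix, 1e-30, None))))

    weights = simplex_weights(neg_loglik, C, alive)
    cv_ll = np.array(
        [float(np.mean(np.log(np.clip(F[:, ci], 1e-30, None)))) if alive[ci] else np.nan
         for ci in range(C)]
    )
    fitted = []
    final_w = []
    for ci, (b, place) in enumerate(candidates):
        if not alive[ci] or weights[ci] == 0.0:
            continue
        fitted.append(_HistogramCandidate(b, place, hazard, sl_opts).fit(A, W))
        final_w.append(weights[ci])
    final_w = np.asarray(final_w)
    kept_ll = cv_ll[[ci for ci in range(C) if alive[ci] and weights[ci] > 0]]
    return HistogramDensity(fitted, final_w / final_w.sum(), kept_ll, floor)


def density_eval(g: HistogramDensity, a, w) -> np.ndarray:
    """Density of the stack at ``a`` given covariate row(s) ``w``."""
    w = np.atleast_2d(_as_matrix(w))
    return g.pdf(a, w)
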
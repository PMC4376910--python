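"""Cross-validated convex stacking (super learner) for binary regressions.

All nuisance regressions with a binary response — the outcome regression
Q̄(A,C,W), the missingness mechanism φ(1|W), and the exposure mechanism
g(1|1,W) for binary exposures — are fit by V-fold cross-validated stacking
over a fixed candidate library.  The stack is the convex combination of
candidate predictions whose cross-validated negative Bernoulli log-likelihood
is minimal; under mild conditions this combination performs asymptotically as
well as the best candidate in the library (the oracle property), which is
what makes it a defensible default when the true regression form is unknown.

Default library (six candidates): main-terms logistic regression (GLM),
AIC-based bidirectional stepwise logistic regression (SW), ridge-shrunk
logistic regression standing in for a weakly-informative Bayesian logistic
model (BGLM), a smooth additive model with spline terms for continuous
covariates (GAM), an adaptive hinge-spline learner with logistic calibration
(MARS), and the intercept-only sample mean (MEAN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CandidateSpec",
    "EnsembleFit",
    "sl_fit",
    "sl_predict",
    "register_candidate",
    "DEFAULT_LIBRARY",
    "simplex_weights",
]

EPS = 1e-6
DEFAULT_LIBRARY = ("GLM", "SW", "BGLM", "GAM", "MARS", "MEAN")


@dataclass(frozen=True)
class CandidateSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)


class SLFitError(RuntimeError):
    """All candidates failed, or the response is unusable."""


# ---------------------------------------------------------------------------
# candidate learners


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class _MeanLearner:
    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_proba1(self, X) -> np.ndarray:
        return np.full(len(X), self.p_)


class _GLMLearner:
    def __init__(self, C=None):
        self.C = C  # None => unpenalized

    def fit(self, X, y):
        self.m_ = LogisticRegression(C=np.inf if self.C is None else self.C,
                                     max_iter=2000)
        self.m_.fit(X, y)
        return self

    def predict_proba1(self, X) -> np.ndarray:
        return self.m_.predict_proba(X)[:, 1]


class _StepwiseLearner:
    """AIC-based bidirectional stepwise logistic regression.

    Starts from the intercept-only model, then alternates add-1 / drop-1
    moves, accepting the move with the best AIC improvement until no move
    improves AIC.
    """

    def __init__(self, max_moves: int = 50):
        self.max_moves = max_moves

    @staticmethod
    def _aic(X, y, cols) -> tuple[float, object]:
        import statsmodels.api as sm

        design = sm.add_constant(X[:, cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        return res.aic, res

    def fit(self, X, y):
        X = np.asarray(X, float)
        p = X.shape[1]
        current: list[int] = []
        best_aic, best_res = self._aic(X, y, current)
        for _ in range(self.max_moves):
            moves = []
            for jc in range(p):
                if jc not in current:
                    moves.append(current + [jc])
            for jc in current:
                moves.append([c for c in current if c != jc])
            improved = False
            for cols in moves:
                try:
                    aic, res = self._aic(X, y, cols)
                except Exception:
                    continue
                if aic < best_aic - 1e-9:
                    best_aic, best_res, current, improved = aic, res, cols, True
            if not improved:
                break
        self.cols_, self.res_ = current, best_res
        return self

    def predict_proba1(self, X) -> np.ndarray:
        import statsmodels.api as sm

        X = np.asarray(X, float)
        design = sm.add_constant(X[:, self.cols_], has_constant="add")
        return np.asarray(self.res_.predict(design))


class _GAMLearner:
    """Additive logistic model: B-spline smooths for continuous covariates.

    Columns with few distinct values (binaries, flags) enter linearly.  New
    data are clipped to the training range of each smoothed column so spline
    bases remain valid.
    """

    def __init__(self, df: int = 5, degree: int = 3):
        self.df, self.degree = df, degree

    def fit(self, X, y):
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        X = np.asarray(X, float)
        nuniq = np.array([len(np.unique(X[:, jc])) for jc in range(X.shape[1])])
        self.smooth_cols_ = np.where(nuniq > max(self.df + 2, 6))[0]
        self.lin_cols_ = np.where(nuniq <= max(self.df + 2, 6))[0]
        if self.smooth_cols_.size == 0:
            self.fallback_ = _GLMLearner().fit(X, y)
            return self
        self.fallback_ = None
        self.lo_ = X[:, self.smooth_cols_].min(axis=0)
        self.hi_ = X[:, self.smooth_cols_].max(axis=0)
        self.bs_ = BSplines(
            X[:, self.smooth_cols_],
            df=[self.df] * len(self.smooth_cols_),
            degree=[self.degree] * len(self.smooth_cols_),
        )
        exog = sm.add_constant(X[:, self.lin_cols_], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.res_ = GLMGam(
                y, exog=exog, smoother=self.bs_, family=sm.families.Binomial()
            ).fit()
        return self

    def predict_proba1(self, X) -> np.ndarray:
        import statsmodels.api as sm

        X = np.asarray(X, float)
        if self.fallback_ is not None:
            return self.fallback_.predict_proba1(X)
        Xs = np.clip(X[:, self.smooth_cols_], self.lo_, self.hi_)
        exog = sm.add_constant(X[:, self.lin_cols_], has_constant="add")
        return np.asarray(self.res_.predict(exog=exog, exog_smooth=Xs))


class _HingeSplineLearner:
    """Adaptive hinge-spline regression with a logistic link.

    Forward pass in the multivariate-adaptive-spline style: starting from the
    intercept, repeatedly add the mirrored hinge pair max(x - t, 0),
    max(t - x, 0) (knots at marginal quantiles) that most reduces the
    least-squares residual, then calibrate the selected basis with a logistic
    fit.  A pragmatic small-scale adaptive learner, not a full implementation
    with backward pruning.
    """

    def __init__(self, max_terms: int = 8, n_knots: int = 5):
        self.max_terms, self.n_knots = max_terms, n_knots

    def _basis(self, X) -> np.ndarray:
        cols = [np.ones(len(X))]
        for jc, t, sign in self.terms_:
            z = sign * (X[:, jc] - t)
            cols.append(np.maximum(z, 0.0))
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.terms_: list[tuple[int, float, float]] = []
        qs = np.linspace(0.1, 0.9, self.n_knots)
        cand = []
        for jc in range(X.shape[1]):
            for t in np.unique(np.quantile(X[:, jc], qs)):
                cand.append((jc, float(t)))
        resid = y - y.mean()
        while len(self.terms_) < self.max_terms and cand:
            best, best_rss = None, np.sum(resid**2) - 1e-10
            B0 = self._basis(X)
            for jc, t in cand:
                pair = np.column_stack(
                    [np.maximum(X[:, jc] - t, 0), np.maximum(t - X[:, jc], 0)]
                )
                B = np.column_stack([B0, pair])
                coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
                rss = np.sum((y - B @ coef) ** 2)
                if rss < best_rss - 1e-12:
                    best, best_rss = (jc, t), rss
            if best is None:
                break
            jc, t = best
            self.terms_ += [(jc, t, 1.0), (jc, t, -1.0)]
            cand.remove(best)
            B = self._basis(X)
            coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
            resid = y - B @ coef
        B = self._basis(X)[:, 1:]  # LogisticRegression adds its own intercept
        if B.shape[1] == 0:
            self.logit_ = None
            self.p_ = float(np.mean(y))
        else:
            self.logit_ = LogisticRegression(C=1e4, max_iter=2000).fit(B, y)
        return self

    def predict_proba1(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if self.logit_ is None:
            return np.full(len(X), self.p_)
        return self.logit_.predict_proba(self._basis(X)[:, 1:])[:, 1]


_FACTORIES: dict[str, Callable[..., object]] = {
    "GLM": lambda **kw: _GLMLearner(**kw),
    "SW": lambda **kw: _StepwiseLearner(**kw),
    "BGLM": lambda **kw: _GLMLearner(C=kw.pop("C", 2.0), **kw),
    "GAM": lambda **kw: _GAMLearner(**kw),
    "MARS": lambda **kw: _HingeSplineLearner(**kw),
    "MEAN": lambda **kw: _MeanLearner(),
}


def register_candidate(name: str, factory: Callable[..., object]) -> None:
    """Register a user-supplied candidate (must expose fit / predict_proba1)."""
    _FACTORIES[name] = factory


# ---------------------------------------------------------------------------
# weight selection on the probability simplex


def simplex_weights(
    risk: Callable[[np.ndarray], float], n_comp: int, active: np.ndarray
) -> np.ndarray:
    """Minimize ``risk(w)`` over the probability simplex.

    ``active`` masks components forced to zero (failed candidates).  Starts
    from the uniform point over active components so exact ties resolve to
    equal weights.
    """
    idx = np.where(active)[0]
    if idx.size == 0:
        raise SLFitError("no surviving candidates")
    if idx.size == 1:
        w = np.zeros(n_comp)
        w[idx[0]] = 1.0
        return w

    def restricted(v):
        w = np.zeros(n_comp)
        w[idx] = v
        return risk(w)

    x0 = np.full(idx.size, 1.0 / idx.size)
    res = minimize(
        restricted,
        x0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * idx.size,
        constraints=[{"type": "eq", "fun": lambda v: np.sum(v) - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    v = np.clip(res.x, 0.0, None)
    v /= v.sum()
    # guard: never worse than the best single active component
    singles = []
    for i in range(idx.size):
        e = np.zeros(idx.size)
        e[i] = 1.0
        singles.append(restricted(e))
    best = int(np.argmin(singles))
    if restricted(v) > singles[best] + 1e-10:
        v = np.zeros(idx.size)
        v[best] = 1.0
    w = np.zeros(n_comp)
    w[idx] = v
    return w


# ---------------------------------------------------------------------------
# ensemble fit


@dataclass
class EnsembleFit:
    specs: list[CandidateSpec]
    weights: np.ndarray
    models: list[object]  # refit-on-full-data candidates (None where dropped)
    cv_risks: np.ndarray  # per-candidate CV risk (NaN where dropped)
    ensemble_risk: float
    loss: str
    V: int
    seed: int
    feature_names: list[str] | None = None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"candidate": self.names, "cv_risk": self.cv_risks, "weight": self.weights}
        )


def _risk_fn(loss: str, y: np.ndarray) -> Callable[[np.ndarray], float]:
    if loss == "nll":
        def nll(p):
            p = np.clip(p, EPS, 1 - EPS)
            return -float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return nll
    if loss == "mse":
        return lambda p: float(np.mean((y - p) ** 2))
    raise ValueError(f"unknown loss {loss!r}")


def _coerce_specs(library) -> list[CandidateSpec]:
    specs = []
    for c in library:
        if isinstance(c, CandidateSpec):
            specs.append(c)
        else:
            specs.append(CandidateSpec(str(c)))
    return specs


def sl_fit(
    X,
    y,
    library: Sequence = DEFAULT_LIBRARY,
    V: int = 10,
    seed: int = 0,
    loss: str = "nll",
) -> EnsembleFit:
    """Fit the cross-validated convex stack.

    Folds are stratified on ``y`` so every training fold sees both classes.
    A candidate that raises on any fold (or on the full-data refit) is
    dropped with a warning and receives weight zero.  A degenerate response
    (all 0 or all 1) yields a MEAN-only fit.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    specs = _coerce_specs(library)
    if not specs:
        raise SLFitError("empty candidate library")

    if len(np.unique(y)) < 2:
        warnings.warn("degenerate response; returning MEAN-only fit")
        specs = [CandidateSpec("MEAN")]
        model = _FACTORIES["MEAN"]().fit(X, y)
        return EnsembleFit(
            specs, np.array([1.0]), [model], np.array([np.nan]),
            np.nan, loss, V, seed, feature_names,
        )

    n_min_class = int(min(np.sum(y == 0), np.sum(y == 1)))
    V_eff = max(2, min(V, n_min_class, n))
    skf = StratifiedKFold(n_splits=V_eff, shuffle=True, random_state=seed)
    C = len(specs)
    Z = np.full((n, C), np.nan)
    alive = np.ones(C, dtype=bool)
    for tr, te in skf.split(X, y):
        for ci, spec in enumerate(specs):
            if not alive[ci]:
                continue
            try:
                m = _FACTORIES[spec.name](**spec.hyperparameters).fit(X[tr], y[tr])
                Z[te, ci] = np.clip(m.predict_proba1(X[te]), EPS, 1 - EPS)
            except Exception as exc:  # noqa: BLE001 - candidate isolation
                alive[ci] = False
                warnings.warn(f"candidate {spec.name} dropped: {exc}")
    if not alive.any():
        raise SLFitError("all candidates failed in cross-validation")

    risk_of = _risk_fn(loss, y)
    cv_risks = np.array(
        [risk_of(Z[:, ci]) if alive[ci] else np.nan for ci in range(C)]
    )
    weights = simplex_weights(lambda w: risk_of(Z[:, alive] @ w[alive]), C, alive)
    ensemble_risk = risk_of(Z[:, alive] @ weights[alive])

    models: list[object] = []
    for ci, spec in enumerate(specs):
        if not alive[ci] or weights[ci] == 0.0:
            models.append(None)
            continue
        try:
            models.append(_FACTORIES[spec.name](**spec.hyperparameters).fit(X, y))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"candidate {spec.name} failed on refit: {exc}")
            weights[ci] = 0.0
            models.append(None)
    if weights.sum() == 0:
        raise SLFitError("all candidates failed on refit")
    weights = weights / weights.sum()
    return EnsembleFit(
        specs, weights, models, cv_risks, ensemble_risk, loss, V_eff, seed,
        feature_names,
    )


def sl_predict(fit: EnsembleFit, X_new) -> np.ndarray:
    """Convex-combination prediction, clipped to [1e-6, 1 - 1e-6]."""
    if fit.feature_names is not None and isinstance(X_new, pd.DataFrame):
        if list(X_new.columns) != fit.feature_names:
            raise ValueError("prediction columns do not match training columns")
    X_new = _as_matrix(X_new)
    out = np.zeros(len(X_new))
    for w, m in zip(fit.weights, fit.models):
        if w > 0 and m is not None:
            out += w * np.asarray(m.predict_proba1(X_new))
    return np.clip(out, EPS, 1 - EPS)
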
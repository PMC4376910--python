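"""Cross-validated prediction diagnostics: out-of-fold ROC curves and AUC.

Compares the stacked learner with stepwise logistic regression on the same
fold partition, so differences in the curves reflect the learners and not
the data split.  The AUC is computed by the rank (concordance) formula with
ties counted 1/2, so it is exactly the probability that a randomly chosen
positive case receives a higher score than a randomly chosen negative case.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .superlearner import DEFAULT_LIBRARY, _StepwiseLearner, sl_fit, sl_predict

__all__ = ["cv_predictions", "roc_auc", "compare_learners"]


def cv_predictions(
    X,
    y,
    learner: str = "super_learner",
    V: int = 10,
    seed: int = 0,
    library=DEFAULT_LIBRARY,
) -> np.ndarray:
    """Out-of-fold probability predictions under a shared fold partition.

    Every prediction comes from a model fit that excluded the observation's
    fold; identical ``seed`` gives identical folds across learners.  A fold
    whose fit fails contributes NaN predictions (excluded from ROC, with a
    warning).
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < V:
        raise ValueError("need n >= V")
    V_eff = max(2, min(V, int(min(np.sum(y == 0), np.sum(y == 1)))))
    skf = StratifiedKFold(n_splits=V_eff, shuffle=True, random_state=seed)
    out = np.full(n, np.nan)
    for tr, te in skf.split(X, y):
        try:
            if learner == "super_learner":
                fit = sl_fit(X[tr], y[tr], library=library, V=max(2, V_eff - 1),
                             seed=seed)
                out[te] = sl_predict(fit, X[te])
            elif learner == "stepwise":
                m = _StepwiseLearner().fit(X[tr], y[tr])
                out[te] = m.predict_proba1(X[te])
            else:
                raise ValueError(f"unknown learner {learner!r}")
        except ValueError:
            raise
        except Exception as exc:  # noqa: BLE001 - fold isolation
            warnings.warn(f"fold fit failed and is excluded from ROC: {exc}")
    return out


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Full ROC step curve and the concordance AUC (ties counted 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], labels[order]
    tps = np.cumsum(lab == 1)
    fps = np.cumsum(lab == 0)
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    curve = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[distinct] / n0],
            "tpr": np.r_[0.0, tps[distinct] / n1],
            "threshold": np.r_[np.inf, s[distinct]],
        }
    )
    return curve, float(auc)


def compare_learners(
    X, y, V: int = 10, seed: int = 0, library=DEFAULT_LIBRARY
) -> pd.DataFrame:
    """AUC of the stack vs stepwise logistic on shared folds."""
    rows = []
    for learner in ("super_learner", "stepwise"):
        preds = cv_predictions(X, y, learner, V=V, seed=seed, library=library)
        _, auc = roc_auc(preds, y)
        rows.append({"learner": learner, "auc": auc})
    return pd.DataFrame(rows)
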
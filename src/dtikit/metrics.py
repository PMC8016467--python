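"""Evaluation metrics for binding-affinity regression and interaction classification.

Regression models are scored with mean squared error, the concordance index
(fraction of compound-target pairs whose predicted affinities are ordered the
same way as their measured affinities, ties scoring 1/2) and the Pearson
product-moment correlation.  Classification models are scored with AUROC,
AUPRC and the F1 score at a decision threshold.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "mse",
    "concordance_index",
    "pearson",
    "auroc",
    "auprc",
    "f1",
    "evaluate_predictions",
    "REGRESSION_METRICS",
    "CLASSIFICATION_METRICS",
]

REGRESSION_METRICS = ("mse", "ci", "pearson")
CLASSIFICATION_METRICS = ("auroc", "auprc", "f1")


def _as_1d(y, name: str) -> np.ndarray:
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _paired(y, yhat):
    a = _as_1d(y, "y")
    b = _as_1d(yhat, "yhat")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: y has {a.size}, yhat has {b.size}")
    return a, b


def mse(y, yhat) -> float:
    """Mean squared error between observed and predicted affinities."""
    a, b = _paired(y, yhat)
    return float(np.mean((a - b) ** 2))


def concordance_index(y, yhat) -> float:
    """Concordance index between observed and predicted values.

    Over every pair (i, j) with ``y[i] > y[j]`` the prediction scores 1 when
    ``yhat[i] > yhat[j]``, 1/2 when tied, 0 otherwise; the CI is the average.
    Raises if no strictly ordered pair exists in ``y`` (CI undefined).
    """
    a, b = _paired(y, yhat)
    if a.size < 2:
        raise ValueError("concordance index needs at least 2 observations")
    # vectorized over all ordered pairs; n is modest in this package's use
    dy = a[:, None] - a[None, :]
    comparable = dy > 0
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("concordance index undefined: all y values tied")
    dyhat = b[:, None] - b[None, :]
    wins = (dyhat > 0) & comparable
    ties = (dyhat == 0) & comparable
    return float((wins.sum() + 0.5 * ties.sum()) / n_pairs)


def pearson(y, yhat) -> float:
    """Pearson product-moment correlation; errors on a constant vector."""
    a, b = _paired(y, yhat)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("pearson correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def _check_binary(y) -> np.ndarray:
    a = _as_1d(y, "y")
    if not set(np.unique(a)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary {0,1}")
    if len(np.unique(a)) < 2:
        raise ValueError("both classes must be present")
    return a


def auroc(y, scores) -> float:
    """Area under the ROC curve (rank / Mann-Whitney formulation with ties)."""
    a = _check_binary(y)
    s = _as_1d(scores, "scores")
    if a.shape != s.shape:
        raise ValueError("length mismatch between y and scores")
    return float(_skm.roc_auc_score(a, s))


def auprc(y, scores) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    a = _check_binary(y)
    s = _as_1d(scores, "scores")
    if a.shape != s.shape:
        raise ValueError("length mismatch between y and scores")
    return float(_skm.average_precision_score(a, s))


def f1(y, scores, threshold: float = 0.5) -> float:
    """F1 score of the hard labels obtained at ``scores >= threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    a = _check_binary(y)
    s = _as_1d(scores, "scores")
    if a.shape != s.shape:
        raise ValueError("length mismatch between y and scores")
    pred = (s >= threshold).astype(float)
    return float(_skm.f1_score(a, pred, zero_division=0.0))


def evaluate_predictions(y, yhat, task: str, f1_threshold: float = 0.5) -> dict:
    """Metric map for a prediction vector: task decides the metric set.

    Regression -> {mse, ci, pearson}; classification -> {auroc, auprc, f1}.
    """
    if task == "regression":
        return {
            "mse": mse(y, yhat),
            "ci": concordance_index(y, yhat),
            "pearson": pearson(y, yhat),
        }
    if task == "classification":
        return {
            "auroc": auroc(y, yhat),
            "auprc": auprc(y, yhat),
            "f1": f1(y, yhat, threshold=f1_threshold),
        }
    raise ValueError(f"unknown task {task!r}; expected 'regression' or 'classification'")
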
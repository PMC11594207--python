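"""Calibration-set partitioning, PLS / PLS-DA / random-forest modeling,
and evaluation metrics.

* ``spxy_split`` — Kennard-Stone sample selection on a combined,
  max-normalized X and y distance (the SPXY scheme), so the calibration set
  spans both predictor and response space. Deterministic.
* ``fit_pls`` — NIPALS PLS1 with the latent-variable count chosen by
  venetian-blind k-fold RMSECV (ties to the smaller count).
* ``fit_plsda`` — one-hot PLS2 with argmax decision, count chosen by
  cross-validated accuracy (or RMSECV, configurable).
* ``fit_rft`` — seeded random-forest classifier (scikit-learn ensemble).
* R2 is 1 - SS_res/SS_tot; accuracy is a percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier

from . import _pls
from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "SplitResult", "PLSModel", "PLSDAModel", "EvaluationReport",
    "spxy_split", "fit_pls", "predict_pls", "fit_plsda", "predict_plsda",
    "fit_rft", "predict_rft", "evaluate_regression", "evaluate_classification",
    "venetian_folds", "rmsecv_curve",
]


# ---------------------------------------------------------------------------
# SPXY partitioning

@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        self.calibration_indices = np.asarray(self.calibration_indices, dtype=int)
        self.prediction_indices = np.asarray(self.prediction_indices, dtype=int)


def spxy_split(X: np.ndarray, y: np.ndarray, calibration_fraction: float = 2 / 3
               ) -> SplitResult:
    """SPXY partitioning: Kennard-Stone on d_x/max(d_x) + d_y/max(d_y).

    Seeds with the sample pair at maximal combined distance, then greedily
    adds the sample maximizing its minimum distance to the selected set,
    until the calibration count reaches ``round(n * calibration_fraction)``.
    Ties break to the smallest sample index. Fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ConfigurationError("spxy_split: needs at least 3 samples")
    if not 0 < calibration_fraction < 1:
        raise ConfigurationError("spxy_split: calibration_fraction must be in (0, 1)")
    dx = squareform(pdist(X))
    dy = np.abs(y[:, None] - y[None, :])
    if dx.max() == 0:
        raise DegenerateDataError("spxy_split: all samples identical in X")
    if dy.max() == 0:
        raise DegenerateDataError("spxy_split: response has zero spread")
    d = dx / dx.max() + dy / dy.max()

    n_cal = int(round(n * calibration_fraction))
    n_cal = max(2, min(n_cal, n - 1))
    i, j = np.unravel_index(np.argmax(d), d.shape)  # first maximal pair, row-major
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_cal:
        sub = d[np.ix_(remaining, selected)]
        min_to_sel = sub.min(axis=1)
        best = int(np.argmax(min_to_sel))  # first (=smallest index) among ties
        selected.append(remaining.pop(best))
    cal = np.sort(selected)
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, calibration_fraction)


def venetian_folds(n: int, k: int) -> list[np.ndarray]:
    """Interleaved (venetian-blind) fold assignment: fold j gets rows j, j+k, ..."""
    if k < 2 or k > n:
        raise ConfigurationError(f"venetian_folds: need 2 <= folds <= n, got k={k}, n={n}")
    return [np.arange(j, n, k) for j in range(k)]


# ---------------------------------------------------------------------------
# PLS regression

@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model in original band space."""

    n_lv: int
    weights: np.ndarray       # p x lv
    x_loadings: np.ndarray    # p x lv
    y_loadings: np.ndarray    # lv
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # p

    def to_json(self, path: str | Path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload))


def _check_regression_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if np.std(y) == 0:
        raise DegenerateDataError("fit_pls: response has zero variance")


def rmsecv_curve(X: np.ndarray, y: np.ndarray, max_lv: int, cv_folds: int
                 ) -> np.ndarray:
    """Venetian-blind k-fold RMSECV for component counts 1..max_lv.

    Folds that cannot support ``max_lv`` components contribute predictions at
    their largest achievable count (nested-component predictions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    folds = venetian_folds(n, cv_folds)
    sq_err = np.zeros(max_lv)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt, yt = X[train_idx], y[train_idx]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, Q, a = _pls.nipals(Xt - xm, yt - ym, max_lv)
        Bs = _pls.coefficient_path(W, P, Q)
        Xe = X[test_idx] - xm
        for k in range(max_lv):
            b = Bs[min(k, a - 1)][:, 0]
            pred = Xe @ b + ym
            sq_err[k] += np.sum((y[test_idx] - pred) ** 2)
    return np.sqrt(sq_err / n)


def fit_pls(X_cal: np.ndarray, y_cal: np.ndarray, max_lv: int = 10,
            cv_folds: int = 10) -> tuple[PLSModel, np.ndarray]:
    """Fit PLS1 with the component count minimizing k-fold RMSECV.

    Returns the refit model at the chosen count together with the full
    RMSECV curve (index k-1 holds the k-component error).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    _check_regression_inputs(X_cal, y_cal)
    n, p = X_cal.shape
    fold_sizes = [len(f) for f in venetian_folds(n, cv_folds)]
    cap = min(max_lv, p, n - max(fold_sizes) - 1)
    if cap < 1:
        cap = 1
    rmsecv = rmsecv_curve(X_cal, y_cal, cap, cv_folds)
    n_lv = int(np.argmin(rmsecv)) + 1  # argmin takes the first, i.e. smallest lv
    xm, ym = X_cal.mean(axis=0), y_cal.mean()
    W, P, Q, a = _pls.nipals(X_cal - xm, y_cal - ym, n_lv)
    b = _pls.coefficients(W, P, Q, a)[:, 0]
    model = PLSModel(n_lv=a, weights=W, x_loadings=P, y_loadings=Q[:, 0],
                     x_mean=xm, y_mean=float(ym), coefficients=b)
    return model, rmsecv


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """y_hat = (X_new - x_mean) . b + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p = model.coefficients.shape[0]
    if X_new.shape[1] != p:
        raise ConfigurationError(
            f"predict_pls: expected {p} bands, got {X_new.shape[1]}")
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


# ---------------------------------------------------------------------------
# PLS-DA classification

@dataclass
class PLSDAModel:
    """One-hot PLS2 classifier: predicted class = argmax of the continuous
    prediction; exact ties go to the lower class index (first in sorted
    class order)."""

    classes: np.ndarray
    n_lv: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray    # lv x n_classes
    x_mean: np.ndarray
    y_mean: np.ndarray        # n_classes
    coefficients: np.ndarray  # p x n_classes


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return classes, Y


def fit_plsda(X_cal: np.ndarray, labels: np.ndarray, max_lv: int = 10,
              cv_folds: int = 10, criterion: str = "accuracy"
              ) -> tuple[PLSDAModel, np.ndarray]:
    """Fit PLS-DA with the component count chosen by cross-validation.

    ``criterion="accuracy"`` (default) maximizes CV accuracy; ``"rmsecv"``
    minimizes the RMSE of the one-hot predictions. Ties break to the
    smaller component count. Each class must have at least ``cv_folds``
    members so every fold sees every class.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    labels = np.asarray(labels)
    classes, Y = _one_hot(labels)
    if classes.size < 2:
        raise DegenerateDataError("fit_plsda: needs at least 2 classes")
    counts = Y.sum(axis=0)
    if counts.min() < cv_folds:
        raise ConfigurationError(
            f"fit_plsda: smallest class has {int(counts.min())} members < {cv_folds} folds")
    n, p = X_cal.shape
    folds = venetian_folds(n, cv_folds)
    cap = min(max_lv, p, n - max(len(f) for f in folds) - 1)
    cap = max(cap, 1)

    score = np.zeros(cap)  # accuracy counts or squared errors per lv
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt, Yt = X_cal[train_idx], Y[train_idx]
        xm, ym = Xt.mean(axis=0), Yt.mean(axis=0)
        W, P, Q, a = _pls.nipals(Xt - xm, Yt - ym, cap)
        Bs = _pls.coefficient_path(W, P, Q)
        Xe = X_cal[test_idx] - xm
        for k in range(cap):
            pred = Xe @ Bs[min(k, a - 1)] + ym
            if criterion == "accuracy":
                hit = classes[np.argmax(pred, axis=1)] == labels[test_idx]
                score[k] += hit.sum()
            else:
                score[k] += np.sum((Y[test_idx] - pred) ** 2)
    if criterion == "accuracy":
        n_lv = int(np.argmax(score)) + 1  # first max = smallest lv
        curve = 100.0 * score / n
    else:
        n_lv = int(np.argmin(score)) + 1
        curve = np.sqrt(score / (n * classes.size))

    xm, ym = X_cal.mean(axis=0), Y.mean(axis=0)
    W, P, Q, a = _pls.nipals(X_cal - xm, Y - ym, n_lv)
    B = _pls.coefficients(W, P, Q, a)
    model = PLSDAModel(classes=classes, n_lv=a, weights=W, x_loadings=P,
                       y_loadings=Q, x_mean=xm, y_mean=ym, coefficients=B)
    return model, curve


def predict_plsda(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p = model.coefficients.shape[0]
    if X_new.shape[1] != p:
        raise ConfigurationError(
            f"predict_plsda: expected {p} bands, got {X_new.shape[1]}")
    cont = (X_new - model.x_mean) @ model.coefficients + model.y_mean
    return model.classes[np.argmax(cont, axis=1)]


# ---------------------------------------------------------------------------
# Random forest classification

def fit_rft(X_cal: np.ndarray, labels: np.ndarray, n_trees: int = 500,
            seed: int = 0) -> RandomForestClassifier:
    """Seeded bagged decision-tree ensemble with sqrt(p) features per split."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateDataError("fit_rft: needs at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", criterion="gini",
        random_state=seed, n_jobs=1)
    clf.fit(np.asarray(X_cal, dtype=float), labels)
    return clf


def predict_rft(model: RandomForestClassifier, X_new: np.ndarray) -> np.ndarray:
    return model.predict(np.atleast_2d(np.asarray(X_new, dtype=float)))


# ---------------------------------------------------------------------------
# Metrics and reports

@dataclass
class EvaluationReport:
    """Calibration/prediction metrics in the layout of a results table row."""

    name: str = ""
    r2_cal: float | None = None
    rmse_cal: float | None = None
    r2_pred: float | None = None
    rmse_pred: float | None = None
    accuracy_cal: float | None = None
    accuracy_pred: float | None = None
    n_lv: int | None = None
    hyperparameters: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)
    selected_bands: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls(**json.loads(Path(path).read_text()))


def evaluate_regression(y_true: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """Return (R2, RMSE) with R2 = 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_true.shape != y_hat.shape or y_true.size < 2:
        raise ConfigurationError("evaluate_regression: need equal-length vectors, n >= 2")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateDataError("evaluate_regression: zero-variance y_true")
    ss_res = np.sum((y_true - y_hat) ** 2)
    rmse = float(np.sqrt(np.mean((y_true - y_hat) ** 2)))
    return float(1.0 - ss_res / ss_tot), rmse


def evaluate_classification(labels_true: np.ndarray, labels_hat: np.ndarray) -> float:
    """Percent of correctly classified samples."""
    labels_true = np.asarray(labels_true)
    labels_hat = np.asarray(labels_hat)
    if labels_true.shape != labels_hat.shape or labels_true.size < 2:
        raise ConfigurationError("evaluate_classification: need equal-length vectors, n >= 2")
    return float(100.0 * np.mean(labels_true == labels_hat))
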
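"""RBF-SVM training with (C, gamma) grid search and pooled-CV SE/SP/ACC.

The protocol mirrors standard LIBSVM practice: features are affinely scaled
to [-1, 1] (fitted on the training partition only; constant features map
to 0), the soft-margin cost C and kernel width gamma are chosen by exhaustive
grid search over the classic log2 grid (C in 2^-5..2^15, gamma in
2^-15..2^3, step 2^2) maximizing stratified k-fold CV accuracy, and the
final model is trained on the whole set with the winning pair.  Reported
metrics pool the confusion counts over folds:

    SE = TP/(TP+FN)    SP = TN/(TN+FP)    ACC = (TP+TN)/(TP+FN+TN+FP)

with the positive class the thermophilic one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .encoders import FeatureMatrix

__all__ = [
    "SvmParams",
    "ScalingParams",
    "ConfusionCounts",
    "EvalReport",
    "GridRbfSvm",
    "SvmModel",
    "fit_scaling",
    "grid_search",
    "train",
    "cross_validate",
    "evaluate",
    "default_grid",
]


@dataclass(frozen=True)
class SvmParams:
    """Soft-margin cost C and RBF kernel width gamma (both > 0)."""

    C: float
    g: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g <= 0:
            raise ValueError("C and g must be positive")


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The LIBSVM grid-tool convention: C = 2^-5..2^15, g = 2^-15..2^3, step 2^2."""
    return 2.0 ** np.arange(-5, 16, 2), 2.0 ** np.arange(-15, 4, 2)


@dataclass
class ScalingParams:
    """Per-feature affine map to [-1, 1] fitted on training data.

    Non-constant features map their training min/max to -1/1; constant
    features map identically to 0.
    """

    center: np.ndarray
    halfrange: np.ndarray
    columns: list[str]

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.columns:
                raise ValueError("feature schema mismatch in scaling")
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        safe = np.where(self.halfrange > 0, self.halfrange, 1.0)
        out = (X - self.center) / safe
        out[:, self.halfrange == 0] = 0.0
        return out


def fit_scaling(X: pd.DataFrame) -> ScalingParams:
    values = X.to_numpy(dtype=float)
    lo, hi = values.min(axis=0), values.max(axis=0)
    return ScalingParams(
        center=(lo + hi) / 2.0, halfrange=(hi - lo) / 2.0, columns=list(X.columns)
    )


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def evaluate(confusion: ConfusionCounts) -> tuple[float, float, float]:
    """Return (SE, SP, ACC) from pooled confusion counts.

    SE is NaN (with a warning) when no positives were evaluated, and SP
    likewise for negatives.
    """
    if confusion.total == 0:
        raise ValueError("cannot evaluate an empty confusion table")
    if confusion.TP + confusion.FN == 0:
        warnings.warn("no positive instances; SE undefined", stacklevel=2)
        se = float("nan")
    else:
        se = confusion.TP / (confusion.TP + confusion.FN)
    if confusion.TN + confusion.FP == 0:
        warnings.warn("no negative instances; SP undefined", stacklevel=2)
        sp = float("nan")
    else:
        sp = confusion.TN / (confusion.TN + confusion.FP)
    acc = (confusion.TP + confusion.TN) / confusion.total
    return se, sp, acc


@dataclass
class EvalReport:
    """Pooled confusion counts and SE/SP/ACC for a model under k-fold CV."""

    confusion: ConfusionCounts
    SE: float
    SP: float
    ACC: float
    per_fold: list[dict] = field(default_factory=list)
    params: SvmParams | None = None
    k: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "TP": self.confusion.TP,
                "TN": self.confusion.TN,
                "FP": self.confusion.FP,
                "FN": self.confusion.FN,
            },
            "SE_pct": round(100 * self.SE, 2),
            "SP_pct": round(100 * self.SP, 2),
            "ACC_pct": round(100 * self.ACC, 2),
            "per_fold": self.per_fold,
            "params": {"C": self.params.C, "g": self.params.g} if self.params else None,
            "k": self.k,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _require_labels(data: FeatureMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    if data.y is None:
        raise ValueError("a labeled feature matrix is required")
    y = data.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return data.X, y


def _folds(
    y: np.ndarray, k: int, seed: int | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    if k < 2:
        raise ValueError("k must be >= 2")
    minority = np.bincount(y).min()
    if k > minority:
        raise ValueError(
            f"k={k} exceeds the minority class size {minority}; "
            "reduce k or add data"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _cv_accuracy(
    X: pd.DataFrame,
    y: np.ndarray,
    params: SvmParams,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    scale: bool,
) -> float:
    correct = 0
    for train_idx, test_idx in splits:
        pred = _fit_predict(X, y, train_idx, test_idx, params, scale)
        correct += int(np.sum(pred == y[test_idx]))
    return correct / len(y)


def _fit_predict(
    X: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: SvmParams,
    scale: bool,
) -> np.ndarray:
    X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
    if scale:
        scaler = fit_scaling(X_tr)
        A_tr, A_te = scaler.transform(X_tr), scaler.transform(X_te)
    else:
        A_tr, A_te = X_tr.to_numpy(float), X_te.to_numpy(float)
    clf = SVC(C=params.C, gamma=params.g, kernel="rbf")
    clf.fit(A_tr, y[train_idx])
    return clf.predict(A_te)


def grid_search(
    data: FeatureMatrix,
    grid: tuple[Sequence[float], Sequence[float]] | None = None,
    folds: int = 10,
    seed: int | None = 0,
    scale: bool = True,
) -> tuple[SvmParams, pd.DataFrame]:
    """Exhaustive (C, g) search maximizing stratified k-fold CV accuracy.

    Ties break toward smaller C, then smaller g.  Returns the winning
    parameters and the full grid table for audit.
    """
    X, y = _require_labels(data)
    c_values, g_values = grid if grid is not None else default_grid()
    splits = _folds(y, folds, seed)
    rows = []
    best: tuple[float, float, float] | None = None  # (-acc, C, g) minimized
    for C in sorted(c_values):
        for g in sorted(g_values):
            acc = _cv_accuracy(X, y, SvmParams(C, g), splits, scale)
            rows.append({"C": C, "g": g, "cv_accuracy": acc})
            key = (-acc, C, g)
            if best is None or key < best:
                best = key
    table = pd.DataFrame(rows)
    assert best is not None
    return SvmParams(C=best[1], g=best[2]), table


@dataclass
class SvmModel:
    """A trained RBF-SVM plus the feature schema and scaling it expects."""

    feature_names: list[str]
    scaling: ScalingParams | None
    svc: SVC
    params: SvmParams

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "feature schema mismatch: model was trained on "
                f"{len(self.feature_names)} features "
                f"{self.feature_names[:3]}..., got {list(X.columns)[:3]}..."
            )
        A = self.scaling.transform(X) if self.scaling else X.to_numpy(float)
        return self.svc.predict(A)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError("feature schema mismatch")
        A = self.scaling.transform(X) if self.scaling else X.to_numpy(float)
        return self.svc.decision_function(A)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain an SvmModel")
        return model


def train(
    data: FeatureMatrix, params: SvmParams, scale: bool = True
) -> SvmModel:
    """Train an RBF-SVM on the whole matrix with the given parameters."""
    X, y = _require_labels(data)
    scaler = fit_scaling(X) if scale else None
    A = scaler.transform(X) if scaler else X.to_numpy(float)
    clf = SVC(C=params.C, gamma=params.g, kernel="rbf")
    clf.fit(A, y)
    return SvmModel(list(X.columns), scaler, clf, params)


def cross_validate(
    data: FeatureMatrix,
    params: SvmParams,
    k: int = 10,
    seed: int | None = 0,
    scale: bool = True,
) -> EvalReport:
    """Stratified k-fold CV with per-fold scaling and pooled confusion counts.

    Every instance is predicted exactly once by a model that never saw it;
    scaling is refitted inside each training fold.
    """
    X, y = _require_labels(data)
    splits = _folds(y, k, seed)
    tp = tn = fp = fn = 0
    per_fold = []
    for fold_i, (train_idx, test_idx) in enumerate(splits):
        pred = _fit_predict(X, y, train_idx, test_idx, params, scale)
        truth = y[test_idx]
        f_tp = int(np.sum((pred == 1) & (truth == 1)))
        f_tn = int(np.sum((pred == 0) & (truth == 0)))
        f_fp = int(np.sum((pred == 1) & (truth == 0)))
        f_fn = int(np.sum((pred == 0) & (truth == 1)))
        tp, tn, fp, fn = tp + f_tp, tn + f_tn, fp + f_fp, fn + f_fn
        per_fold.append(
            {"fold": fold_i, "TP": f_tp, "TN": f_tn, "FP": f_fp, "FN": f_fn,
             "accuracy": (f_tp + f_tn) / len(test_idx)}
        )
    confusion = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    se, sp, acc = evaluate(confusion)
    return EvalReport(confusion, se, sp, acc, per_fold, params, k, seed)


class GridRbfSvm(ClassifierMixin, BaseEstimator):
    """sklearn-style RBF-SVM classifier with built-in (C, gamma) grid search.

    Parameters
    ----------
    c_grid, gamma_grid : sequences of float, optional
        Candidate values; default is the classic LIBSVM log2 grid.
    cv : int, default 10
        Stratified fold count for the grid search.
    scale : bool, default True
        Affine [-1, 1] scaling fitted on training data (constant features
        map to 0).
    random_state : int, optional
        Seed for the CV shuffling.

    Attributes
    ----------
    best_params_ : SvmParams
    grid_table_ : pandas.DataFrame
        CV accuracy at every grid point.
    model_ : SvmModel
        The final model trained on all data with ``best_params_``.
    """

    def __init__(
        self,
        c_grid: Sequence[float] | None = None,
        gamma_grid: Sequence[float] | None = None,
        cv: int = 10,
        scale: bool = True,
        random_state: int | None = 0,
    ) -> None:
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.scale = scale
        self.random_state = random_state

    def _as_matrix(self, X, y=None) -> FeatureMatrix:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"f{j}" for j in range(X.shape[1])]
        return FeatureMatrix(X, y)

    def fit(self, X, y) -> "GridRbfSvm":
        data = self._as_matrix(X, y)
        grid = None
        if self.c_grid is not None or self.gamma_grid is not None:
            c_default, g_default = default_grid()
            grid = (
                np.asarray(self.c_grid if self.c_grid is not None else c_default),
                np.asarray(self.gamma_grid if self.gamma_grid is not None else g_default),
            )
        self.best_params_, self.grid_table_ = grid_search(
            data, grid=grid, folds=self.cv, seed=self.random_state, scale=self.scale
        )
        self.model_ = train(data, self.best_params_, scale=self.scale)
        self.classes_ = np.unique(np.asarray(data.y))
        self.feature_names_in_ = np.asarray(data.X.columns, dtype=object)
        self.n_features_in_ = data.X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        data = self._as_matrix(X)
        return self.model_.predict(data.X)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        data = self._as_matrix(X)
        return self.model_.decision_function(data.X)
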
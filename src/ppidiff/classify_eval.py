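"""Baseline SVM classification of protein pairs and evaluation metrics.

Metrics are computed from the confusion matrix:

* ``Accuracy = (TP + TN) / (TP + TN + FP + FN)``
* ``Recall   = TP / (TP + FN)``  (sensitivity on the interacting class)
* ``F1       = 2*TP / (2*TP + FP + FN)``
* ``MCC      = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``

MCC with any zero marginal factor is 0 by convention (chance level).
Evaluation averages the per-fold metrics over stratified shuffled 80/20
splits, reporting both the per-fold values and their unweighted means.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .feature_selection import (
    SelectionError,
    SelectionResult,
    make_folds,
    standardize_features,
)

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """A metric is undefined for the given confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts for a binary classification outcome."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified pairs."""
    if cm.total == 0:
        raise MetricError("accuracy undefined on an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def compute_recall(cm: ConfusionMatrix) -> float:
    """Fraction of interacting pairs correctly identified."""
    if cm.tp + cm.fn == 0:
        raise MetricError("recall undefined with no positive instances")
    return cm.tp / (cm.tp + cm.fn)


def compute_f1(cm: ConfusionMatrix) -> float:
    """F1 score, ``2*TP / (2*TP + FP + FN)``."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise MetricError("F1 undefined with no positives predicted or present")
    return 2 * cm.tp / denom


def compute_mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on degenerate marginals."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold metrics and their unweighted means."""

    accuracy: float
    recall: float
    f1: float
    mcc: float
    per_fold: tuple[dict[str, float], ...]
    n_folds: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "recall": self.recall,
                "f1": self.f1,
                "mcc": self.mcc,
                "n_folds": self.n_folds,
                "per_fold": list(self.per_fold),
            },
            indent=2,
        )

    def summary_row(self, features_label: str) -> str:
        """One-line TSV row: Features, Accuracy, Recall, MCC, F1."""
        return (
            f"{features_label}\t{self.accuracy:.4g}\t{self.recall:.4g}"
            f"\t{self.mcc:.4g}\t{self.f1:.4g}"
        )


class PairInteractionClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM baseline over a (selected) pair difference matrix.

    Standardizes features with training statistics, then fits a linear SVM
    at regularization ``c``.  Deterministic given the data and parameters.
    An RBF kernel is available via ``kernel="rbf"``.
    """

    def __init__(self, c: float = 0.1, kernel: str = "linear"):
        self.c = c
        self.kernel = kernel

    def fit(self, X, y) -> "PairInteractionClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise SelectionError("training rows contain a single class")
        X_std, self.mean_, self.sd_ = standardize_features(X)
        self.model_ = SVC(C=self.c, kernel=self.kernel, random_state=0)
        self.model_.fit(X_std, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        return self.model_.predict(X)


def train_baseline(
    X_train: np.ndarray, y_train: np.ndarray, c: float = 0.1,
    kernel: str = "linear",
) -> PairInteractionClassifier:
    """Fit the baseline classifier on consensus-restricted training rows."""
    if np.asarray(X_train).shape[1] == 0:
        raise SelectionError(
            "no features to train on; run feature selection first"
        )
    return PairInteractionClassifier(c=c, kernel=kernel).fit(X_train, y_train)


def evaluate(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    selection: SelectionResult | Sequence[str],
    n_folds: int = 15,
    seed: int = 0,
    test_fraction: float = 0.2,
    c: float | None = None,
) -> MetricsReport:
    """Average the four metrics over stratified shuffled 80/20 splits.

    The design matrix is restricted to the consensus features, then for
    each fold a baseline SVM is trained on the 80% side and scored on the
    20% side.  Headline numbers are unweighted means of the per-fold
    values.  *seed* governs the evaluation splits and is independent of the
    selection seed (fresh splits by default).
    """
    if isinstance(selection, SelectionResult):
        features = list(selection.consensus_features)
        if c is None:
            c = (
                selection.chosen_regularization
                if selection.config.method == "svm"
                else 0.1
            )
    else:
        features = list(selection)
    if c is None:
        c = 0.1
    if not features:
        raise SelectionError(
            "empty consensus feature set; run feature selection first"
        )
    if isinstance(X, pd.DataFrame):
        missing = [f for f in features if f not in X.columns]
        if missing:
            raise SelectionError(f"features missing from matrix: {missing[:5]}")
        X_sel = X[features].to_numpy(dtype=float)
    else:
        X_sel = np.asarray(X, dtype=float)

    y = np.asarray(y).astype(int)
    folds = make_folds(y, n_folds, test_fraction, seed)
    per_fold: list[dict[str, float]] = []
    for i, (train, test) in enumerate(folds):
        try:
            clf = train_baseline(X_sel[train], y[train], c=c)
            y_pred = clf.predict(X_sel[test])
        except Exception as exc:
            raise RuntimeError(f"evaluation failed in fold {i}: {exc}") from exc
        cm = ConfusionMatrix.from_predictions(y[test], y_pred)
        per_fold.append(
            {
                "accuracy": compute_accuracy(cm),
                "recall": compute_recall(cm),
                "f1": compute_f1(cm),
                "mcc": compute_mcc(cm),
            }
        )
    means = {
        k: float(np.mean([f[k] for f in per_fold]))
        for k in ("accuracy", "recall", "f1", "mcc")
    }
    return MetricsReport(
        accuracy=means["accuracy"],
        recall=means["recall"],
        f1=means["f1"],
        mcc=means["mcc"],
        per_fold=tuple(per_fold),
        n_folds=n_folds,
    )
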
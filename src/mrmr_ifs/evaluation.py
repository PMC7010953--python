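"""Leave-one-out cross-validation and the confusion-matrix metric stack.

LOOCV covers classifier training only: the gene ranking is computed once on
the full dataset, outside the CV loop. This mirrors the two-stage procedure
being modelled (rank first, then evaluate prefixes), and carries the usual
selection-bias caveat — the cross-validated MCC of a prefix is optimistic
about generalisation to samples that did not inform the ranking.

Metrics from a 2x2 confusion matrix:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    ACC = (TP + TN) / N
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is the headline metric because the positive class is rare (~4%) and
MCC trades off sensitivity and specificity under imbalance. When any MCC
denominator factor is zero (a degenerate predictor), MCC is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifiers import ClassifierSpec, fit_predict
from .data import ConfusionMatrix

__all__ = [
    "MetricSet",
    "metrics",
    "loocv",
    "loocv_predictions",
    "knn_loocv_predictions",
    "confusion_from_predictions",
]


@dataclass(frozen=True)
class MetricSet:
    Sn: float
    Sp: float
    ACC: float
    MCC: float
    source: ConfusionMatrix

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Metrics at reporting precision; full precision is kept internally."""
        return {
            "Sn": round(self.Sn, ndigits),
            "Sp": round(self.Sp, ndigits),
            "ACC": round(self.ACC, ndigits),
            "MCC": round(self.MCC, ndigits),
        }


def metrics(c: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("all-zero confusion matrix")
    if c.n_positive < 1 or c.n_negative < 1:
        raise ValueError("need at least one actual positive and one actual negative")
    sn = c.TP / c.n_positive
    sp = c.TN / c.n_negative
    acc = (c.TP + c.TN) / c.total
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricSet(Sn=sn, Sp=sp, ACC=acc, MCC=mcc, source=c)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def loocv_predictions(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Naive LOOCV: one prediction per sample, each from a model retrained
    on the other N-1 samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    preds = np.empty(n, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_y = y[mask]
        if len(np.unique(train_y)) < 2:
            raise ValueError(
                f"fold {i} (sample index {i}) has a single-class training set; "
                "a class has exactly one member"
            )
        preds[i] = fit_predict(spec, X[mask], train_y, X[i : i + 1])[0]
        mask[i] = True
    return preds


def knn_loocv_predictions(X: np.ndarray, y: np.ndarray, k: int,
                          d2: np.ndarray | None = None) -> np.ndarray:
    """Vectorised kNN LOOCV from a (precomputed) squared-distance matrix.

    Equivalent to naive per-fold retraining: leaving sample i out and
    predicting it is exactly a k-nearest-neighbour vote among the other
    N-1 points. ``d2`` allows the caller to reuse / incrementally update
    the pairwise squared distances across feature prefixes.
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if d2 is None:
        X = np.asarray(X, dtype=float)
        sq = (X ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.maximum(d2, 0.0, out=d2)
    else:
        d2 = d2.copy()
    np.fill_diagonal(d2, np.inf)
    if k == 1:
        nearest = np.argmin(d2, axis=1)
        return y[nearest].astype(np.int64)
    idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
    votes = y[idx].sum(axis=1)
    return (2 * votes > k).astype(np.int64)


def loocv(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> ConfusionMatrix:
    """LOOCV confusion matrix for one classifier spec on one feature matrix."""
    preds = loocv_predictions(spec, X, y)
    return confusion_from_predictions(np.asarray(y).astype(int), preds)
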
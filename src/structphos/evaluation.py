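"""Binary-classification metrics and the tenfold cross-validation harness.

Metrics follow the standard confusion-table formulas: sensitivity (recall)
TP/(TP+FN), specificity TN/(FP+TN), precision TP/(TP+FP), the Matthews-style
correlation coefficient CC = (TP*TN - FP*FN)/sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),
F1 = 2*Pre*Rec/(Pre+Rec), accuracy (TP+TN)/total and the area under the ROC
curve.  Any metric whose denominator vanishes is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    cc: float
    f1: float
    accuracy: float
    auc: float | None = None
    zero_denominator: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "cc": self.cc,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metric_set(c: ConfusionCounts) -> MetricSet:
    """All confusion-table metrics (AUC excluded: it needs scores)."""
    flags: list[str] = []
    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity", flags)
    spe = _ratio(c.tn, c.fp + c.tn, "specificity", flags)
    pre = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    cc_den = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    if cc_den == 0:
        flags.append("cc")
        cc = 0.0
    else:
        cc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(cc_den)
    f1 = _ratio(2 * pre * sen, pre + sen, "f1", flags)
    acc = _ratio(c.tp + c.tn, c.total, "accuracy", flags)
    return MetricSet(
        sensitivity=sen, specificity=spe, precision=pre,
        cc=cc, f1=f1, accuracy=acc, zero_denominator=flags,
    )


def roc_auc(scores, y_true) -> float:
    """Normalised area under the ROC curve (ties by trapezoid)."""
    yt = np.asarray(y_true).astype(int)
    if len(set(yt.tolist())) < 2:
        raise ValueError("AUC undefined for single-class truth")
    return float(roc_auc_score(yt, np.asarray(scores, dtype=float)))


def tenfold_cv(
    X,
    y,
    fit_predict,
    seed: int = 0,
    n_folds: int = 10,
    stratify: bool = True,
):
    """Cross-validate a fit/predict callable.

    ``fit_predict(X_train, y_train, X_test) -> (labels, scores)`` is invoked
    once per fold; feature selection or model fitting must happen inside the
    callable, so nothing leaks from test folds.  Returns (per-fold MetricSet
    list, aggregate MetricSet computed from summed counts with AUC pooled
    over all held-out scores).
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if stratify and np.bincount(y).min() < n_folds:
        import warnings

        warnings.warn("fewer positives than folds; stratified folds will be degenerate")
    cls = StratifiedKFold if stratify else KFold
    splitter = cls(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet] = []
    tp = fp = tn = fn = 0
    pooled_scores = np.empty(len(y))
    tested = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in splitter.split(X, y):
        labels, scores = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        c = confusion(y[test_idx], labels)
        m = metric_set(c)
        if len(set(y[test_idx].tolist())) == 2:
            m.auc = roc_auc(scores, y[test_idx])
        fold_metrics.append(m)
        tp, fp, tn, fn = tp + c.tp, fp + c.fp, tn + c.tn, fn + c.fn
        pooled_scores[test_idx] = scores
        tested[test_idx] = True
    assert tested.all(), "every row must be tested exactly once"
    aggregate = metric_set(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    aggregate.auc = roc_auc(pooled_scores, y)
    return fold_metrics, aggregate
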
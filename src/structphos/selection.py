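"""Two-step feature selection: Gini-importance ranking, then SVM-wrapper SBE.

Step 1 trains a random forest and ranks features by the mean decrease in
Gini impurity (MDGI), standardised to Z-scores

    z_i = (x_i - mean(x)) / sd(x)        (sample SD; all zero when sd = 0)

keeping the top 80.  Step 2 runs sequential backward elimination with an
RBF-SVM wrapper: at every step each single-feature removal is scored by the
composite criterion

    Rc(i) = (1/k) * sum_j { AUC_j + Accu_j + Sen_j + Spe_j }

over k repeats of tenfold cross-validation on the subset excluding feature
i; the argmax removal is applied, down to one feature.  The selected subset
is the Rc-maximising point of the whole elimination path (ties favour the
larger subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from structphos.errors import DegenerateLabelError
from structphos.evaluation import confusion, metric_set, roc_auc


@dataclass
class MDGIRanking:
    table: pd.DataFrame  # columns: feature, mdgi, z, rank
    retained: list[str]


def zscores(x: np.ndarray) -> np.ndarray:
    """Standardise with sample SD (ddof=1); constant vectors map to zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def mdgi_rank(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
    top_m: int = 80,
) -> MDGIRanking:
    """Rank features by random-forest mean-decrease-Gini Z-score; keep top_m.

    Ties in Z are broken by original column order.  ``top_m`` larger than
    the feature count is clamped with a warning.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("mdgi_rank needs both classes present")
    if top_m > X.shape[1]:
        import warnings

        warnings.warn(f"top_m={top_m} exceeds feature count {X.shape[1]}; clamped")
        top_m = X.shape[1]
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X.values, y)
    mdgi = forest.feature_importances_
    z = zscores(mdgi)
    order = np.lexsort((np.arange(len(z)), -z))  # descending z, ties by slot order
    rank = np.empty(len(z), dtype=int)
    rank[order] = np.arange(1, len(z) + 1)
    table = pd.DataFrame(
        {"feature": X.columns, "mdgi": mdgi, "z": z, "rank": rank}
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    retained = table["feature"].head(top_m).tolist()
    return MDGIRanking(table=table, retained=retained)


# --------------------------------------------------------------------------
# Sequential backward elimination


@dataclass
class SBETrace:
    steps: list[tuple[str | None, float]] = field(default_factory=list)
    best_subset: list[str] = field(default_factory=list)
    best_rc: float = float("-inf")
    k: int = 1
    n_evaluations: int = 0


def default_svm_evaluator(svm_config: dict | None = None, n_folds: int = 10):
    """Rc component metrics from stratified tenfold CV of an RBF SVM.

    The default C is deliberately small (see the wrapper-calibration section
    of the methods note): the wrapper must *degrade* when irrelevant
    features are present, and a strongly regularised SVM keeps the Rc
    criterion off its ceiling so elimination retains a gradient.
    """
    cfg = {"kernel": "rbf", "C": 0.3, "gamma": "auto"}
    cfg.update(svm_config or {})

    def evaluate(X: np.ndarray, y: np.ndarray, seed: int) -> dict[str, float]:
        import sklearn

        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        tp = fp = tn = fn = 0
        scores = np.empty(len(y))
        with sklearn.config_context(assume_finite=True):
            for tr, te in folds.split(X, y):
                clf = SVC(**cfg, random_state=seed)
                clf.fit(X[tr], y[tr])
                df = clf.decision_function(X[te])
                # binary SVC: positive decision value <=> classes_[1]
                labels = clf.classes_[(df > 0).astype(int)]
                c = confusion(y[te], labels)
                tp, fp, tn, fn = tp + c.tp, fp + c.fp, tn + c.tn, fn + c.fn
                scores[te] = df
        from structphos.evaluation import ConfusionCounts

        m = metric_set(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        return {
            "auc": roc_auc(scores, y),
            "accuracy": m.accuracy,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
        }

    return evaluate


def composite_criterion(metrics: list[dict[str, float]]) -> float:
    """Rc: mean over repeats of AUC + accuracy + sensitivity + specificity."""
    k = len(metrics)
    return sum(
        m["auc"] + m["accuracy"] + m["sensitivity"] + m["specificity"] for m in metrics
    ) / k


def sbe_select(
    X: pd.DataFrame,
    y,
    k: int = 1,
    seed: int = 0,
    evaluator=None,
) -> SBETrace:
    """Full backward-elimination path; the best subset maximises Rc.

    ``evaluator(X_subset, y, seed) -> {'auc','accuracy','sensitivity',
    'specificity'}`` defaults to stratified tenfold CV of an RBF SVM.  Each
    repeat j of the k repeats uses a distinct fold seed derived from
    ``seed``, and the fold partition is re-drawn at every elimination step:
    comparisons within a step stay paired on a common partition, while a
    feature that merely flatters one particular partition loses its
    advantage at the next step instead of surviving the whole path.  Ties
    in the path argmax keep the larger subset.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("sbe_select needs both classes present")
    if X.shape[1] < 2:
        raise ValueError("sbe_select needs at least 2 features")
    evaluator = evaluator or default_svm_evaluator()
    trace = SBETrace(k=k)
    Xv = np.ascontiguousarray(X.values, dtype=float)
    col_index = {c: i for i, c in enumerate(X.columns)}
    step_no = 0

    def rc_of(features: list[str]) -> float:
        Xs = Xv[:, [col_index[f] for f in features]]
        return composite_criterion(
            [
                evaluator(Xs, y, (seed * 1009 + 9176 * step_no + 7 * j) % 2**31)
                for j in range(k)
            ]
        )

    current = list(X.columns)
    rc_full = rc_of(current)
    trace.steps.append((None, rc_full))
    trace.best_subset, trace.best_rc = list(current), rc_full
    while len(current) > 1:
        step_no += 1
        best_feature, best_rc = None, float("-inf")
        # reversed: columns arrive ordered by step-1 importance, so exact Rc
        # ties drop the least-important feature rather than the most
        for f in reversed(current):
            candidate = [c for c in current if c != f]
            rc = rc_of(candidate)
            trace.n_evaluations += 1
            if rc > best_rc:
                best_feature, best_rc = f, rc
        current = [c for c in current if c != best_feature]
        trace.steps.append((best_feature, best_rc))
        # strict > keeps the earlier (larger) subset on ties
        if best_rc > trace.best_rc:
            trace.best_subset, trace.best_rc = list(current), best_rc
    return trace
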
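"""Imbalance-aware SVM ensemble with asymmetric bootstrap and majority vote.

Phosphorylated residues are rare, so a single classifier trained on the raw
labels over-predicts the majority class.  The ensemble draws n balanced
subsets: each keeps every minority sample and pairs it with an equal-size
resample (with replacement) of the majority class.  One RBF-kernel SVM is
trained per subset and predictions are fused by majority vote; the vote
fraction doubles as a continuous score for ROC analysis.  Tied votes go to
the positive class, favouring sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.svm import SVC

from structphos.errors import DegenerateLabelError


@dataclass
class BootstrapPlan:
    n: int
    seed: int
    minority_label: int
    subsets: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    # each subset: (minority indices -- all of them, majority resample indices)


@dataclass
class EnsembleModel:
    feature_names: list[str] | None
    models: list[SVC]
    plan: BootstrapPlan
    svm_config: dict

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "EnsembleModel":
        return joblib.load(path)


def asymmetric_bootstrap(y, n: int = 5, seed: int = 0) -> BootstrapPlan:
    """n subsets: all minority indices + an equal-size majority resample each."""
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelError("asymmetric_bootstrap needs both classes")
    minority_label = int(classes[np.argmin(counts)])
    minority = np.nonzero(y == minority_label)[0]
    majority = np.nonzero(y != minority_label)[0]
    rng = np.random.default_rng(seed)
    plan = BootstrapPlan(n=n, seed=seed, minority_label=minority_label)
    for _ in range(n):
        draw = rng.choice(majority, size=len(minority), replace=True)
        plan.subsets.append((minority.copy(), draw))
    return plan


def train_ensemble(
    X,
    y,
    plan: BootstrapPlan,
    svm_config: dict | None = None,
    feature_names: list[str] | None = None,
) -> EnsembleModel:
    """One RBF SVM per bootstrap subset, trained only on that subset's rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cfg = {"kernel": "rbf", "C": 1.0, "gamma": "auto"}
    cfg.update(svm_config or {})
    models: list[SVC] = []
    for minority, majority in plan.subsets:
        idx = np.concatenate([minority, majority])
        assert len(np.unique(y[idx])) == 2, "bootstrap subset lost a class"
        clf = SVC(**cfg, random_state=plan.seed)
        clf.fit(X[idx], y[idx])
        models.append(clf)
    return EnsembleModel(
        feature_names=feature_names, models=models, plan=plan, svm_config=cfg
    )


def predict_vote(model: EnsembleModel, X) -> tuple[np.ndarray, np.ndarray]:
    """(labels, vote fractions); label positive iff fraction >= 1/2 (ties up)."""
    X = np.asarray(X, dtype=float)
    votes = np.stack([clf.predict(X) for clf in model.models])  # (n, rows)
    fraction = (votes == 1).mean(axis=0)
    labels = (fraction >= 0.5).astype(int)
    return labels, fraction
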
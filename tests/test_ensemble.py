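"""Asymmetric bootstrap, SVM sub-models and majority-vote fusion."""

import numpy as np
import pytest
from sklearn.svm import SVC

from structphos.ensemble import (
    asymmetric_bootstrap,
    predict_vote,
    train_ensemble,
)
from structphos.errors import DegenerateLabelError


def imbalanced_labels(n_min=3, n_maj=10):
    return np.array([1] * n_min + [0] * n_maj)


class TestBootstrap:
    def test_every_subset_keeps_all_minority_and_equal_majority(self):
        y = imbalanced_labels(3, 10)
        plan = asymmetric_bootstrap(y, n=5, seed=0)
        minority = set(np.nonzero(y == 1)[0])
        for minor, major in plan.subsets:
            assert set(minor) == minority
            assert len(major) == len(minority)
            assert all(y[i] == 0 for i in major)

    def test_single_subset_balanced_classes(self):
        y = imbalanced_labels(5, 5)
        plan = asymmetric_bootstrap(y, n=1, seed=1)
        minor, major = plan.subsets[0]
        assert len(minor) + len(major) == 10

    def test_different_seeds_differ(self):
        y = imbalanced_labels(5, 40)
        same = 0
        for trial in range(20):
            a = asymmetric_bootstrap(y, n=1, seed=trial)
            b = asymmetric_bootstrap(y, n=1, seed=1000 + trial)
            if np.array_equal(np.sort(a.subsets[0][1]), np.sort(b.subsets[0][1])):
                same += 1
        assert same <= 1

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelError):
            asymmetric_bootstrap(np.ones(10), n=3, seed=0)


def separable_data(n=40, seed=0, imbalance=0.25):
    rng = np.random.default_rng(seed)
    n_pos = int(n * imbalance)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X = rng.normal(scale=0.3, size=(n, 2))
    X[y == 1] += [4.0, 4.0]
    return X, y


class TestTrainAndVote:
    def test_separable_data_perfect_submodels(self):
        X, y = separable_data()
        plan = asymmetric_bootstrap(y, n=5, seed=3)
        model = train_ensemble(X, y, plan)
        for clf, (minor, major) in zip(model.models, plan.subsets):
            idx = np.concatenate([minor, major])
            assert (clf.predict(X[idx]) == y[idx]).all()

    def test_n1_ensemble_equals_single_svm(self):
        X, y = separable_data(seed=5)
        plan = asymmetric_bootstrap(y, n=1, seed=7)
        model = train_ensemble(X, y, plan)
        labels, fraction = predict_vote(model, X)
        minor, major = plan.subsets[0]
        idx = np.concatenate([minor, major])
        single = SVC(kernel="rbf", C=1.0, gamma="auto", random_state=7).fit(X[idx], y[idx])
        assert (labels == single.predict(X)).all()

    def test_identical_subsets_identical_outputs(self):
        X, y = separable_data(seed=2)
        plan = asymmetric_bootstrap(y, n=3, seed=9)
        plan.subsets = [plan.subsets[0]] * 3
        model = train_ensemble(X, y, plan)
        preds = [clf.predict(X) for clf in model.models]
        assert all((p == preds[0]).all() for p in preds)

    def test_deterministic_given_seed(self):
        X, y = separable_data(seed=4)
        out = []
        for _ in range(2):
            plan = asymmetric_bootstrap(y, n=4, seed=11)
            model = train_ensemble(X, y, plan)
            out.append(predict_vote(model, X))
        assert (out[0][0] == out[1][0]).all()
        np.testing.assert_array_equal(out[0][1], out[1][1])


class TestVoteRule:
    class _Stub:
        def __init__(self, votes):
            self._v = np.asarray(votes)

        def predict(self, X):
            return self._v

    def _model_with_votes(self, per_model_votes):
        from structphos.ensemble import BootstrapPlan, EnsembleModel

        models = [self._Stub(v) for v in per_model_votes]
        plan = BootstrapPlan(n=len(per_model_votes), seed=0, minority_label=1)
        return EnsembleModel(feature_names=None, models=models, plan=plan, svm_config={})

    def test_majority_vote_fraction(self):
        model = self._model_with_votes([[1], [1], [1], [0], [0]])
        labels, frac = predict_vote(model, np.zeros((1, 2)))
        assert labels[0] == 1 and frac[0] == pytest.approx(0.6)

    def test_unanimous_negative(self):
        model = self._model_with_votes([[0]] * 5)
        labels, frac = predict_vote(model, np.zeros((1, 2)))
        assert labels[0] == 0 and frac[0] == 0.0

    def test_even_tie_goes_positive(self):
        model = self._model_with_votes([[1], [1], [0], [0]])
        labels, frac = predict_vote(model, np.zeros((1, 2)))
        assert labels[0] == 1 and frac[0] == pytest.approx(0.5)

    def test_fraction_matches_exhaustive_count(self):
        rng = np.random.default_rng(31)
        votes = rng.integers(0, 2, size=(7, 9))
        model = self._model_with_votes(list(votes))
        labels, frac = predict_vote(model, np.zeros((9, 2)))
        np.testing.assert_allclose(frac, votes.mean(axis=0))
        np.testing.assert_array_equal(labels, (votes.mean(axis=0) >= 0.5).astype(int))


class TestImbalanceBenefit:
    def test_ensemble_recall_beats_raw_svm_at_similar_specificity(self):
        """Bootstrap-balanced ensembles recover minority recall lost to imbalance."""
        from structphos.synthetic import SynthConfig, synth_dataset

        rec_ens, rec_raw, spe_ens, spe_raw = [], [], [], []
        for seed in range(5):
            X, y, _ = synth_dataset(
                SynthConfig(n_sites=300, n_features=20, n_planted=5,
                            delta=1.2, pos_fraction=0.1, seed=seed)
            )
            rng = np.random.default_rng(seed)
            test = rng.random(len(y)) < 0.33
            Xtr, ytr, Xte, yte = X[~test].values, y[~test], X[test].values, y[test]
            plan = asymmetric_bootstrap(ytr, n=5, seed=seed)
            model = train_ensemble(Xtr, ytr, plan)
            labels, _ = predict_vote(model, Xte)
            raw = SVC(kernel="rbf", C=1.0, gamma="auto").fit(Xtr, ytr).predict(Xte)
            from structphos.evaluation import confusion, metric_set

            m_ens = metric_set(confusion(yte, labels))
            m_raw = metric_set(confusion(yte, raw))
            rec_ens.append(m_ens.sensitivity)
            rec_raw.append(m_raw.sensitivity)
            spe_ens.append(m_ens.specificity)
            spe_raw.append(m_raw.specificity)
        assert np.mean(rec_ens) >= np.mean(rec_raw)
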
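"""One-vs-one SVM contracts, ROC/AUC against a pair-count oracle, and the
repeated hold-out bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import emgtcd as E
from emgtcd.classify import f1_from_confusion
from emgtcd.errors import ParameterError, ValidationError

from conftest import mann_whitney_auc


def gaussian_clusters(rng, centers, n=30, spread=0.1):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(c, spread, size=(n, len(c))))
        y += [label] * n
    return np.vstack(X), np.array(y)


FOUR_CENTERS = {
    "NC": (0.0, 0.0), "LF": (4.0, 0.0), "TR": (0.0, 4.0), "SE": (4.0, 4.0),
}


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestTrainPredict:
    def test_separable_clusters_fit_perfectly(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        model = E.train_svm(X, y)
        pred, _ = E.predict(model, X)
        assert np.all(pred == y)
        assert len(model.models_) == 6  # 4 choose 2 pairwise classifiers

    def test_duplicated_rows_same_decision(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        probe = rng.normal(2.0, 1.0, size=(20, 2))
        a = E.train_svm(X, y)
        b = E.train_svm(np.vstack([X, X]), np.concatenate([y, y]))
        pa, _ = E.predict(a, probe)
        pb, _ = E.predict(b, probe)
        assert np.all(pa == pb)

    def test_deterministic(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        probe = rng.normal(2.0, 2.0, size=(50, 2))
        p1, s1 = E.predict(E.train_svm(X, y, E.SvmConfig(seed=3)), probe)
        p2, s2 = E.predict(E.train_svm(X, y, E.SvmConfig(seed=3)), probe)
        assert np.all(p1 == p2)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_centroid_probe_gets_its_label(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        model = E.train_svm(X, y)
        for label, c in FOUR_CENTERS.items():
            pred, _ = E.predict(model, np.array([c]))
            assert pred[0] == label

    def test_scores_for_all_trained_classes(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        model = E.train_svm(X, y)
        probe = X[y == "SE"][:3]  # only one class present at prediction
        _, scores = E.predict(model, probe)
        assert list(scores.columns) == ["NC", "LF", "TR", "SE"]

    def test_tie_resolved_by_summed_scores(self, rng):
        # equilateral 3-class geometry: the center probe draws one vote
        # per class; the contract resolves via summed decision values
        centers = {"NC": (0.0, 1.0), "LF": (-0.866, -0.5), "TR": (0.866, -0.5)}
        X, y = gaussian_clusters(rng, centers, n=40, spread=0.05)
        model = E.train_svm(X, y, E.SvmConfig(scale_features=False))
        probe = np.zeros((1, 2))
        pred, scores = E.predict(model, probe)
        votes = model._votes.iloc[0]
        tied = [c for c in model.classes_ if votes[c] == votes.max()]
        best = max(scores.iloc[0][c] for c in tied)
        winners = [c for c in tied if scores.iloc[0][c] == best]
        assert pred[0] == winners[0]

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError):
            E.train_svm(X, np.array(["NC"] * 10))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS)
        model = E.train_svm(X, y)
        with pytest.raises(ValidationError, match="dimension"):
            E.predict(model, rng.normal(size=(4, 5)))


class TestRocAuc:
    def test_indicator_scores_give_unit_auc(self):
        labels = np.array(["SE"] * 5 + ["NC"] * 5)
        scores = pd.DataFrame({"SE": [1.0] * 5 + [0.0] * 5})
        out = E.roc_auc_one_vs_rest(scores, labels)
        assert out["SE"]["auc"] == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        labels = np.array(["SE"] * 4 + ["NC"] * 6)
        scores = pd.DataFrame({"SE": np.zeros(10)})
        assert E.roc_auc_one_vs_rest(scores, labels)["SE"]["auc"] == \
            pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        labels = rng.choice(["SE", "NC"], size=20)
        labels[:2] = ["SE", "NC"]  # both classes present
        scores = pd.DataFrame({"SE": rng.normal(size=20).round(1)})  # ties too
        got = E.roc_auc_one_vs_rest(scores, labels)["SE"]["auc"]
        want = mann_whitney_auc(scores["SE"].tolist(), labels == "SE")
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.choice(["SE", "NC"], size=40)
        labels[:2] = ["SE", "NC"]
        s = rng.normal(size=40)
        a = E.roc_auc_one_vs_rest(pd.DataFrame({"SE": s}), labels)["SE"]["auc"]
        b = E.roc_auc_one_vs_rest(
            pd.DataFrame({"SE": np.exp(3 * s)}), labels)["SE"]["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_class_undefined(self):
        labels = np.array(["SE"] * 5)
        scores = pd.DataFrame({"SE": np.arange(5.0)})
        assert np.isnan(E.roc_auc_one_vs_rest(scores, labels)["SE"]["auc"])

    def test_roc_endpoints_and_monotonicity(self, rng):
        labels = rng.choice(["SE", "NC"], size=30)
        labels[:2] = ["SE", "NC"]
        scores = pd.DataFrame({"SE": rng.normal(size=30)})
        roc = E.roc_auc_one_vs_rest(scores, labels)["SE"]["roc"]
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)


def feature_matrix_from(X, y):
    return E.FeatureMatrix(
        values=pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])]),
        labels=y,
        window_index=[("r", i) for i in range(len(y))],
    )


class TestHoldout:
    def test_confusion_totals_count_test_samples(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS, n=25)
        fm = feature_matrix_from(X, y)
        rep = E.holdout_evaluate(fm, repeats=10)
        assert rep.confusion.sum() == 10 * 4 * 5  # repeats x classes x 20%
        assert rep.confusion.shape == (4, 4)

    def test_f1_identity_on_single_repeat(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS, n=25, spread=2.0)
        fm = feature_matrix_from(X, y)
        rep = E.holdout_evaluate(fm, repeats=1)
        for i, cls in enumerate(rep.classes):
            tp = rep.confusion[i, i]
            prec = tp / rep.confusion[:, i].sum()
            rec = tp / rep.confusion[i].sum()
            want = 2 * prec * rec / (prec + rec) if prec + rec else np.nan
            assert rep.f1[cls] == pytest.approx(want, abs=1e-12)
            assert f1_from_confusion(rep.confusion, i) == \
                pytest.approx(want, abs=1e-12)

    def test_small_class_rejected_by_name(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS, n=10)
        y[y == "TR"][:0]  # no-op; shrink TR below 5 rows
        keep = np.concatenate([np.flatnonzero(y != "TR"),
                               np.flatnonzero(y == "TR")[:4]])
        fm = feature_matrix_from(X[keep], y[keep])
        with pytest.raises(ValidationError, match="TR"):
            E.holdout_evaluate(fm)

    def test_invalid_fraction(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS, n=6)
        with pytest.raises(ParameterError):
            E.holdout_evaluate(feature_matrix_from(X, y), train_fraction=1.0)

    def test_trial_level_split_separates_recordings(self, rng):
        X, y = gaussian_clusters(rng, FOUR_CENTERS, n=24)
        rids = [f"{lbl}{i % 6}" for i, lbl in enumerate(y)]
        fm = E.FeatureMatrix(
            values=pd.DataFrame(X, columns=["a", "b"]),
            labels=y,
            window_index=[(r, i) for i, r in enumerate(rids)],
        )
        rep = E.holdout_evaluate(fm, repeats=3, trial_level=True)
        assert 0.0 <= rep.overall_accuracy_mean <= 1.0
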
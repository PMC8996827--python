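"""Classification/regression harnesses and evaluation metrics."""

import numpy as np
import pytest

from drfp_kit.errors import (
    ConstantTruth,
    EmptyTrainingSet,
    LabelEncodingError,
    TooFewRows,
)
from drfp_kit.models import (
    GbmHyperparams,
    GradientBoostingYieldRegressor,
    KnnReactionClassifier,
    MlpReactionClassifier,
    confusion_entropy,
    confusion_matrix,
    evaluate_classification,
    evaluate_regression,
    matthews_corrcoef_multiclass,
)


def reference_cen(C):
    """Literal transcription of the confusion-entropy definition."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if n < 2 or C.sum() == 0:
        return 0.0
    base = 2.0 * (n - 1)
    cen = 0.0
    for j in range(n):
        denom = C[j, :].sum() + C[:, j].sum()
        if denom == 0:
            continue
        P_j = denom / (2.0 * C.sum())
        h = 0.0
        for k in range(n):
            if k == j:
                continue
            for p in (C[j, k] / denom, C[k, j] / denom):
                if p > 0:
                    h -= p * np.log(p) / np.log(base)
        cen += P_j * h
    return cen


class TestKnn:
    def test_single_row_dominates(self):
        X = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        model = KnnReactionClassifier().fit(X, np.array(["a"]))
        assert model.predict(np.array([[0, 1, 0, 1]], dtype=np.uint8))[0] == "a"

    def test_self_query_distance_zero(self):
        rng = np.random.default_rng(2)
        X = (rng.random((20, 64)) < 0.3).astype(np.uint8)
        model = KnnReactionClassifier(n_neighbors=1).fit(X, np.arange(20))
        dist, idx = model.kneighbors(X[:5], n_neighbors=1)
        np.testing.assert_array_equal(idx.ravel(), np.arange(5))
        np.testing.assert_allclose(dist, 0)

    def test_majority_vote(self):
        # 1 query bit pattern nearest to three 'a' rows, two 'b' rows
        X = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 1], [1, 1, 1, 0], [0, 0, 1, 1], [0, 1, 1, 1]],
            dtype=np.uint8,
        )
        y = np.array(["a", "a", "a", "b", "b"])
        model = KnnReactionClassifier(n_neighbors=5).fit(X, y)
        assert model.predict(np.array([[1, 1, 0, 0]], dtype=np.uint8))[0] == "a"

    def test_tie_broken_by_summed_distance(self):
        # 2 votes each; class 'b' rows are strictly closer
        X = np.array(
            [[1, 1, 1, 1], [1, 1, 1, 0], [0, 1, 1, 1], [0, 0, 0, 1]], dtype=np.uint8
        )
        y = np.array(["a", "b", "b", "a"])
        model = KnnReactionClassifier(n_neighbors=4).fit(X, y)
        assert model.predict(np.array([[1, 1, 1, 1]], dtype=np.uint8))[0] == "b"

    def test_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        X = (rng.random((60, 128)) < 0.2).astype(np.uint8)
        y = rng.integers(0, 3, size=60)
        Q = (rng.random((25, 128)) < 0.2).astype(np.uint8)
        model = KnnReactionClassifier(n_neighbors=5).fit(X, y)
        _, idx = model.kneighbors(Q)
        # brute-force pairwise Hamming scan, stable order
        D = (Q[:, None, :] != X[None, :, :]).sum(axis=2)
        for q in range(25):
            mine = D[q, idx[q]]
            best = np.sort(D[q])[:5]
            np.testing.assert_array_equal(np.sort(mine), best)

    def test_k_clipped_to_n(self, caplog):
        X = np.eye(3, dtype=np.uint8)
        model = KnnReactionClassifier(n_neighbors=4).fit(X, np.array(list("abc")))
        with caplog.at_level("WARNING"):
            model.predict(X[:1])
        assert "clipping" in caplog.text

    def test_empty_training_set(self):
        with pytest.raises(EmptyTrainingSet):
            KnnReactionClassifier().fit(np.zeros((0, 4)), np.array([]))


class TestMlp:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(0)
        # disjoint bit blocks: linearly separable by construction
        X = np.zeros((60, 64), dtype=np.uint8)
        y = np.repeat([0, 1, 2], 20)
        for i, c in enumerate(y):
            block = slice(c * 20, c * 20 + 20)
            X[i, block] = (rng.random(20) < 0.6).astype(np.uint8)
        model = MlpReactionClassifier(random_state=1).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        assert model.n_epochs_ == 10

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = (rng.random((40, 32)) < 0.3).astype(np.uint8)
        y = rng.integers(0, 2, size=40)
        p1 = MlpReactionClassifier(random_state=5).fit(X, y).predict(X)
        p2 = MlpReactionClassifier(random_state=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(LabelEncodingError):
            MlpReactionClassifier().fit(np.zeros((5, 8)), np.zeros(5))


class TestGbm:
    def test_constant_target(self):
        rng = np.random.default_rng(1)
        X = (rng.random((80, 32)) < 0.3).astype(np.uint8)
        y = np.full(80, 50.0)
        model = GradientBoostingYieldRegressor(random_state=0).fit(X, y)
        pred = model.predict(X)
        assert np.abs(pred - 50.0).max() < 0.5

    def test_seeded_split_and_best_round_reproducible(self):
        rng = np.random.default_rng(4)
        X = (rng.random((100, 64)) < 0.3).astype(np.uint8)
        y = 40 + 20 * X[:, 3] + rng.normal(0, 1, 100)
        m1 = GradientBoostingYieldRegressor(random_state=9).fit(X, y)
        m2 = GradientBoostingYieldRegressor(random_state=9).fit(X, y)
        np.testing.assert_array_equal(m1.validation_indices_, m2.validation_indices_)
        assert m1.best_iteration_ == m2.best_iteration_

    def test_validation_rows_disjoint_from_training(self):
        rng = np.random.default_rng(4)
        X = (rng.random((50, 16)) < 0.5).astype(np.uint8)
        y = rng.random(50) * 100
        model = GradientBoostingYieldRegressor(random_state=2).fit(X, y)
        val = model.validation_indices_
        assert len(val) == 5 and len(set(val)) == 5
        assert model.best_iteration_ <= GbmHyperparams().n_estimators

    def test_too_few_rows(self):
        with pytest.raises(TooFewRows):
            GradientBoostingYieldRegressor().fit(np.zeros((3, 4)), np.zeros(3))

    def test_hyperparameter_defaults(self):
        hp = GbmHyperparams()
        assert hp.n_estimators == 999_999
        assert hp.learning_rate == 0.01
        assert hp.max_depth == 15
        assert hp.min_child_weight == 8
        assert hp.colsample_bytree == 0.2125
        assert hp.subsample == 1
        assert hp.early_stopping_rounds == 20
        assert hp.validation_fraction == 0.10


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = evaluate_classification(list("aabbcc"), list("aabbcc"))
        assert m["accuracy"] == 1.0 and m["mcc"] == 1.0 and m["cen"] == 0.0

    def test_binary_worked_example(self):
        # 2x2 confusion [[40,10],[10,40]]: closed-form MCC = 0.6
        truth = [0] * 50 + [1] * 50
        pred = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        m = evaluate_classification(truth, pred)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["mcc"] == pytest.approx(0.6)

    def test_constant_prediction_on_balanced_classes(self):
        m = evaluate_classification([0, 0, 1, 1], [0, 0, 0, 0])
        assert m["accuracy"] == 0.5 and m["mcc"] == 0.0

    def test_mcc_matches_sklearn_on_random_matrices(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(17)
        for _ in range(30):
            n_cls = rng.integers(2, 6)
            truth = rng.integers(0, n_cls, size=200)
            pred = rng.integers(0, n_cls, size=200)
            C, _ = confusion_matrix(truth, pred, labels=np.arange(n_cls))
            assert matthews_corrcoef_multiclass(C) == pytest.approx(
                matthews_corrcoef(truth, pred), abs=1e-9
            )

    def test_cen_matches_literal_definition(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n_cls = int(rng.integers(2, 7))
            C = rng.integers(0, 30, size=(n_cls, n_cls))
            assert confusion_entropy(C) == pytest.approx(reference_cen(C), abs=1e-9)

    def test_cen_zero_iff_diagonal(self):
        assert confusion_entropy(np.diag([5, 8, 2])) == 0.0
        assert confusion_entropy([[5, 1], [0, 5]]) > 0.0


class TestRegressionMetrics:
    def test_exact_and_mean_baselines(self):
        y = np.array([1.0, 2.0, 3.0])
        assert evaluate_regression(y, y)["r2"] == 1.0
        assert evaluate_regression(y, np.full(3, 2.0))["r2"] == 0.0

    def test_worked_example(self):
        # SS_res = 100, SS_tot = 200
        assert evaluate_regression([0, 10, 20], [0, 10, 30])["r2"] == 0.5

    def test_constant_truth_rejected(self):
        with pytest.raises(ConstantTruth):
            evaluate_regression([5, 5, 5], [1, 2, 3])
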
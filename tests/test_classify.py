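import numpy as np
import pandas as pd
import pytest

from valenscope.classify import (
    ClassifierConfig,
    aggregate_cohort,
    knn_predict,
    loocv_evaluate,
)
from valenscope.errors import DegenerateTaskError
from valenscope.reference import REFERENCE_MEANS, load_reference_accuracies


def brute_force_knn(train_X, train_y, query, k):
    """Independent oracle: full distance sort with explicit tie rules."""
    dists = [float(np.linalg.norm(row - query)) for row in train_X]
    order = sorted(range(len(dists)), key=lambda i: (dists[i], i))
    neighbors = order[:k]
    votes = {}
    for i in neighbors:
        votes[train_y[i]] = votes.get(train_y[i], 0) + 1
    top = max(votes.values())
    tied = {lbl for lbl, v in votes.items() if v == top}
    for i in neighbors:
        if train_y[i] in tied:
            return train_y[i]


class TestKnnPredict:
    def test_majority_vote(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = ["A", "A", "A", "B", "B", "B"]
        assert knn_predict(X, y, np.array([1.5]), k=5) == "A"

    def test_query_on_training_point_k1(self):
        X = np.array([[0.0], [5.0]])
        assert knn_predict(X, ["A", "B"], np.array([5.0]), k=1) == "B"

    def test_vote_tie_broken_by_nearest_tied_class(self):
        # three classes, 2-2-1 votes, nearest neighbor belongs to class A
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = ["A", "B", "A", "B", "C"]
        assert knn_predict(X, y, np.array([-0.1]), k=5) == "A"

    def test_k_exceeds_training(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(np.zeros((3, 1)), ["A", "A", "B"], np.zeros(1), k=5)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(3, 21))
            d = int(rng.integers(1, 5))
            k = int(rng.integers(1, n + 1))
            X = np.round(rng.standard_normal((n, d)), 2)  # induce distance ties
            y = [str(lbl) for lbl in rng.integers(0, 3, size=n)]
            query = np.round(rng.standard_normal(d), 2)
            assert knn_predict(X, y, query, k) == brute_force_knn(X, y, query, k)


class TestLoocv:
    def test_separated_clusters_reach_100(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))]
        )
        y = ["low"] * 20 + ["high"] * 20
        result = loocv_evaluate(X, y, ClassifierConfig(kind="knn"))
        assert result.accuracy == 100.0

    def test_permuted_labels_fall_in_chance_band(self):
        """With labels independent of features, LOOCV accuracy lies inside
        the binomial 99% band around 50% (n=40 -> [27.5%, 72.5%])."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 2))
        y = list(rng.permutation(["low"] * 20 + ["high"] * 20))
        result = loocv_evaluate(X, y, ClassifierConfig(kind="knn"))
        assert 27.5 <= result.accuracy <= 72.5

    def test_fold_predictions_match_manual_oracle(self):
        """Six 1-D points, kNN k=1, no standardization: every fold's
        prediction equals the label of the nearest remaining point."""
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = ["A", "A", "A", "B", "B", "B"]
        config = ClassifierConfig(kind="knn", k=1, standardize=False)
        result = loocv_evaluate(X, y, config)
        expected = []
        for i in range(6):
            rest = [j for j in range(6) if j != i]
            nearest = min(rest, key=lambda j: (abs(X[j, 0] - X[i, 0]), j))
            expected.append(y[nearest])
        assert result.predictions == expected
        assert result.accuracy == 100.0

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateTaskError):
            loocv_evaluate(np.zeros((4, 1)), ["A"] * 4)

    def test_runs_are_bit_identical(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 2))
        y = ["low"] * 6 + ["high"] * 6
        config = ClassifierConfig(
            kind="svm_rbf", tuner="bayesian", tuner_iters=6, inner_folds=3,
            tuner_seed=7,
        )
        r1 = loocv_evaluate(X, y, config)
        r2 = loocv_evaluate(X, y, config)
        assert r1.predictions == r2.predictions
        for d1, d2 in zip(r1.fold_details, r2.fold_details):
            assert d1["hyperparameters"] == d2["hyperparameters"]

    @pytest.mark.parametrize("tuner", ["grid", "bayesian"])
    def test_svm_separable_toy_reaches_100(self, tuner):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(-2, 0.2, (10, 2)), rng.normal(2, 0.2, (10, 2))]
        )
        y = ["low"] * 10 + ["high"] * 10
        config = ClassifierConfig(
            kind="svm_rbf", tuner=tuner, tuner_iters=9, inner_folds=3
        )
        assert loocv_evaluate(X, y, config).accuracy == 100.0

    @pytest.mark.parametrize("kind", ["knn", "svm_rbf"])
    def test_held_out_trial_cannot_leak(self, kind):
        """Perturbing the held-out trial must leave that fold's scaler
        statistics and tuned hyperparameters exactly unchanged."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 2))
        y = ["low"] * 5 + ["high"] * 5
        config = ClassifierConfig(
            kind=kind, tuner="grid", tuner_iters=4, inner_folds=2
        )
        baseline = loocv_evaluate(X, y, config)
        X_perturbed = X.copy()
        X_perturbed[3] = 1e6  # extreme held-out value for fold 3
        perturbed = loocv_evaluate(X_perturbed, y, config)
        d0, d1 = baseline.fold_details[3], perturbed.fold_details[3]
        np.testing.assert_array_equal(d0["scaler_mean"], d1["scaler_mean"])
        np.testing.assert_array_equal(d0["scaler_scale"], d1["scaler_scale"])
        if kind == "svm_rbf":
            assert d0["hyperparameters"] == d1["hyperparameters"]

    def test_log_transform_targets_power_columns_only(self):
        from valenscope.classify import _prepare_matrix

        table = pd.DataFrame(
            {"alpha_activity": [1.0, 10.0, 100.0],
             "alpha_psd": [1.0, 100.0, 10000.0],
             "alpha_mobility": [0.1, 0.2, 0.3]}
        )
        config = ClassifierConfig(kind="knn", log_transform_power_features=True)
        X = _prepare_matrix(table, config)
        np.testing.assert_allclose(X[:, 0], [0.0, 1.0, 2.0])  # activity logged
        np.testing.assert_allclose(X[:, 1], [0.0, 2.0, 4.0])  # psd logged
        np.testing.assert_allclose(X[:, 2], [0.1, 0.2, 0.3])  # mobility raw


class TestAggregate:
    def test_simple_mean(self):
        assert aggregate_cohort([100.0, 90.0]) == 95.00

    def test_two_decimal_half_up_reporting(self):
        assert aggregate_cohort([97.1875] * 4) == 97.19

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cohort([])

    def test_reference_table_reproduces_published_averages(self):
        """Averaging the bundled per-subject reference accuracies
        reproduces the published cohort means to two decimals."""
        table = load_reference_accuracies()
        assert len(table) == 32
        for column, expected in REFERENCE_MEANS.items():
            assert aggregate_cohort(table[column]) == expected
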
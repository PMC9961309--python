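import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgmtpmp.classification import (
    FoldPlan,
    KNNClassifier,
    KNNConfig,
    SVMConfig,
    cross_validate,
    cross_validate_fn,
    knn_predict,
    minkowski_distance,
    stratified_folds,
    stratified_split,
    stratified_split_counts,
    svm_predict,
    svm_train,
)

vec = st.lists(st.floats(-50, 50), min_size=3, max_size=3)


class TestMinkowskiDistance:
    @pytest.mark.parametrize(
        "q, x, r, expected",
        [
            ((0, 0), (3, 4), 2, 5.0),
            ((1, 2, 3), (1, 2, 3), 3, 0.0),
            ((0, 0), (1, 1), 1, 2.0),
        ],
    )
    def test_examples(self, q, x, r, expected):
        assert minkowski_distance(q, x, r) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            minkowski_distance([0], [0, 1], 2)

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            minkowski_distance([0], [1], 0.5)

    @given(vec, vec, vec, st.sampled_from([1.0, 1.5, 2.0, 3.0]))
    def test_metric_axioms(self, a, b, c, r):
        a, b, c = map(np.array, (a, b, c))
        dab = minkowski_distance(a, b, r)
        assert dab >= 0
        assert minkowski_distance(a, a, r) == 0
        assert dab == pytest.approx(minkowski_distance(b, a, r))
        assert dab <= (
            minkowski_distance(a, c, r) + minkowski_distance(c, b, r) + 1e-9
        )


class TestKNN:
    def test_query_on_training_point_k1(self):
        y, _ = knn_predict([[0, 0], [5, 5]], [0, 1], [5, 5], KNNConfig(k=1))
        assert y == 1

    def test_majority_vote(self):
        y, score = knn_predict(
            [[0, 0], [1, 0], [2, 0]], [0, 1, 1], [0.9, 0], KNNConfig(k=3)
        )
        assert y == 1 and score == pytest.approx(2 / 3)

    def test_weighted_vote_prefers_near_neighbor(self):
        # weights 1/d^2: distances (1, 2, 60), labels (0, 1, 1)
        # V(0) = 1 > V(1) = 0.25 + 1/3600
        y, _ = knn_predict(
            [[1, 0], [2, 0], [60, 0]], [0, 1, 1], [0, 0],
            KNNConfig(k=3, vote="weighted", weight_exponent=2),
        )
        assert y == 0

    def test_weighted_vote_k3_eq5_arithmetic(self):
        train = np.array([[1.0, 0], [2.0, 0], [50.0, 0]])
        clf = KNNClassifier(
            KNNConfig(k=3, vote="weighted", weight_exponent=2)
        ).fit(train, np.array([0, 1, 1]))
        y, s = clf.predict([[0.0, 0]])
        # V(0) = 1/1 = 1; V(1) = 1/4 + 1/2500
        assert y[0] == 0
        assert s[0] == pytest.approx((0.25 + 1 / 2500) / (1.25 + 1 / 2500))

    def test_zero_distance_under_weighted_voting(self):
        y, _ = knn_predict(
            [[3, 3], [0, 0], [1, 1]], [1, 0, 0], [3, 3],
            KNNConfig(k=3, vote="weighted"),
        )
        assert y == 1  # exact match decides directly despite 2-vs-1 labels

    def test_vote_tie_broken_by_nearest(self):
        train = [[1, 0], [2, 0], [3, 0], [10, 0]]
        labels = [1, 0, 0, 1]
        y, _ = knn_predict(train, labels, [0, 0], KNNConfig(k=3))
        # neighbors at distances 1,2,3 with labels 1,0,0 -> majority 0
        assert y == 0
        y2, _ = knn_predict([[1, 0], [2, 0]], [1, 0], [0, 0], KNNConfig(k=1))
        assert y2 == 1

    def test_leave_in_k1_is_perfect(self, rng):
        x = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        clf = KNNClassifier(KNNConfig(k=1)).fit(x, y)
        pred, _ = clf.predict(x)
        assert np.array_equal(pred, y)

    def test_agrees_with_sklearn_on_random_data(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        x = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        q = rng.normal(size=(15, 6))
        mine, _ = KNNClassifier(KNNConfig(k=5)).fit(x, y).predict(q)
        sk = KNeighborsClassifier(n_neighbors=5).fit(x, y).predict(q)
        assert np.array_equal(mine, sk)

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            KNNClassifier(KNNConfig(k=5)).fit(np.zeros((3, 2)), np.zeros(3, int))

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            KNNConfig(k=2)

    @pytest.mark.parametrize(
        "distance", ["euclidean", "minkowski", "chebyshev-as-printed",
                     "mahalanobis", "euclidean-printed"]
    )
    def test_all_distance_variants_run(self, rng, distance):
        x = rng.normal(size=(20, 4))
        y = rng.integers(0, 2, 20)
        clf = KNNClassifier(KNNConfig(k=1, distance=distance)).fit(x, y)
        pred, _ = clf.predict(x)
        assert np.array_equal(pred, y)  # leave-in holds for every metric


class TestSVM:
    def test_separable_clusters_linear_kernel(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = svm_train(x, y, SVMConfig(kernel="linear"))
        pred, _ = model.predict(x)
        assert np.array_equal(pred, y)
        assert len(model.support_vectors_) >= 2

    def test_xor_needs_nonlinear_kernel(self, rng):
        base = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], float)
        x = np.repeat(base, 20, axis=0) + rng.normal(0, 0.05, (80, 2))
        y = np.repeat([0, 0, 1, 1], 20)
        acc = {}
        for kernel in ("linear", "rbf"):
            pred, _ = svm_train(x, y, SVMConfig(kernel=kernel)).predict(x)
            acc[kernel] = (pred == y).mean()
        assert acc["rbf"] > acc["linear"]
        assert acc["linear"] <= 0.8  # balanced XOR caps linear separation

    def test_conflicting_duplicate_labels_still_train(self):
        x = np.array([[0.0, 0], [0.0, 0], [1.0, 1]])
        y = np.array([0, 1, 1])
        model = svm_train(x, y)  # soft margin absorbs the contradiction
        label, score = svm_predict(model, [1.0, 1])
        assert label in (0, 1) and np.isfinite(score)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            svm_train(np.zeros((5, 2)), np.zeros(5, int))

    @pytest.mark.parametrize("kernel", ["poly2", "poly3", "poly4"])
    def test_polynomial_kernels_run(self, rng, kernel):
        x = rng.normal(size=(30, 3))
        y = (x[:, 0] > 0).astype(int)
        pred, _ = svm_train(x, y, SVMConfig(kernel=kernel)).predict(x)
        assert (pred == y).mean() > 0.8


class TestStratifiedFolds:
    def test_balanced_folds_on_60_40(self):
        y = [0] * 60 + [1] * 40
        plan = stratified_folds(y, 10, seed=3)
        for fold in plan.folds:
            labels = np.array(y)[fold]
            assert (labels == 0).sum() == 6 and (labels == 1).sum() == 4

    def test_same_seed_same_plan(self):
        y = [0] * 30 + [1] * 30
        a = stratified_folds(y, 10, seed=5)
        b = stratified_folds(y, 10, seed=5)
        assert all(np.array_equal(f1, f2) for f1, f2 in zip(a.folds, b.folds))

    def test_pigeonhole_on_unbalanced_sizes(self):
        y = [0] * 101 + [1] * 100
        plan = stratified_folds(y, 10, seed=0)
        for cls in (0, 1):
            counts = [np.sum(np.array(y)[f] == cls) for f in plan.folds]
            assert max(counts) - min(counts) <= 1

    def test_partition_is_exact(self):
        y = [0] * 25 + [1] * 35
        plan = stratified_folds(y, 10, seed=1)
        seen = np.concatenate(plan.folds)
        assert sorted(seen) == list(range(60))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            stratified_folds([0] * 20 + [1] * 5, 10, seed=0)

    def test_overlapping_folds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldPlan([np.array([0, 1]), np.array([1, 2])])


class TestStratifiedSplit:
    def test_published_class_sizes_produce_printed_totals(self):
        counts = stratified_split_counts({0: 111960, 1: 141931}, 0.8)
        assert counts["train"] == {0: 89568, 1: 113545}
        assert counts["train_total"] == 203113
        assert counts["test_total"] == 50778

    def test_split_indices_match_counts(self):
        y = [0] * 50 + [1] * 30
        tr, te = stratified_split(y, 0.8, seed=2)
        assert len(tr) == 40 + 24 and len(te) == 16
        assert sorted(np.concatenate([tr, te])) == list(range(80))


class TestCrossValidate:
    def test_oracle_classifier_scores_perfectly(self):
        y = np.array([0] * 30 + [1] * 30)

        def fold_fn(train_idx, test_idx):
            return y[test_idx], y[test_idx].astype(float)

        res = cross_validate_fn(y, fold_fn, k=10, seed=0)
        assert res.mean_accuracy == 100.0 and res.accuracy_sd == 0.0

    def test_two_fold_aggregate_arithmetic(self):
        # fold accuracies 80 and 90 -> 85 +- sqrt(2*25/1)
        y = np.array([0] * 20 + [1] * 20)
        state = {"i": 0}

        def fold_fn(train_idx, test_idx):
            wrong = 4 if state["i"] == 0 else 2
            state["i"] += 1
            pred = y[test_idx].copy()
            pred[:wrong] ^= 1
            return pred, pred.astype(float)

        res = cross_validate_fn(y, fold_fn, k=2, seed=0)
        assert res.mean_accuracy == pytest.approx(85.0)
        assert res.accuracy_sd == pytest.approx(np.sqrt(50), abs=1e-9)

    def test_coin_flip_near_chance(self):
        y = np.array([0] * 100 + [1] * 100)
        flip_rng = np.random.default_rng(0)

        def fold_fn(train_idx, test_idx):
            pred = flip_rng.integers(0, 2, len(test_idx))
            return pred, pred.astype(float)

        res = cross_validate_fn(y, fold_fn, k=10, seed=0)
        # binomial sd at fold size 20 is ~11 percentage points
        assert abs(res.mean_accuracy - 50.0) < 12

    def test_normalization_fit_inside_fold(self, phantom_small):
        from mgmtpmp.radiomic import glcm_feature_vector

        imgs, labels = phantom_small
        x = np.stack([glcm_feature_vector(i) for i in imgs])
        res = cross_validate(
            x, labels, lambda: KNNClassifier(KNNConfig(k=1)), k=10, seed=0
        )
        assert res.mean_accuracy > 80.0  # phantom classes recoverable from GLCM
        assert len(res.fold_metrics) == 10
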
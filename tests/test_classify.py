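import numpy as np
import pytest

from hive.classify import (CVConfig, CVResult, evaluate, evaluate_holdout,
                           holdout_split, stratified_folds)
from hive.records import FeatureMatrix


def gaussian_matrix(n_pos=50, n_neg=50, n_features=10, separation=5.0,
                    seed=0) -> FeatureMatrix:
    """Two Gaussian classes at +/- separation/2 on every feature axis."""
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n_pos, n_features)) + separation / 2
    neg = rng.standard_normal((n_neg, n_features)) - separation / 2
    X = np.vstack([pos, neg])
    y = np.array([1] * n_pos + [0] * n_neg)
    order = rng.permutation(len(y))
    ids = [f"img_{i:03d}" for i in range(len(y))]
    return FeatureMatrix(ids, [f"f{i}" for i in range(n_features)],
                         X[order], class_labels=y[order])


class TestStratifiedFolds:
    def test_divisible_classes_exact_counts(self):
        y = np.array([1] * 20 + [0] * 30)
        folds = stratified_folds(y, k=10, seed=0)
        for f in range(10):
            assert np.sum((folds == f) & (y == 1)) == 2
            assert np.sum((folds == f) & (y == 0)) == 3

    def test_unbalanced_243_331_within_one(self):
        # 243 positives and 331 negatives across 10 folds
        y = np.array([1] * 243 + [0] * 331)
        folds = stratified_folds(y, k=10, seed=1)
        pos_counts = [int(np.sum((folds == f) & (y == 1))) for f in range(10)]
        neg_counts = [int(np.sum((folds == f) & (y == 0))) for f in range(10)]
        assert set(pos_counts) <= {24, 25} and sum(pos_counts) == 243
        assert set(neg_counts) <= {33, 34} and sum(neg_counts) == 331

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        a = stratified_folds(y, 4, seed=9)
        b = stratified_folds(y, 4, seed=9)
        c = stratified_folds(y, 4, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1] * 3 + [0] * 30)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_folds(y, 10, seed=0)


class TestEvaluate:
    def test_separable_gaussians_reach_perfect_macc(self):
        matrix = gaussian_matrix(seed=42)
        result = evaluate(matrix, CVConfig(k=10, seed=0))
        assert result.mAcc == 1.0
        # linear-boundary oracle: the midpoint hyperplane alone is perfect
        scores = matrix.values.sum(axis=1)
        assert np.all((scores > 0) == (matrix.class_labels == 1))

    def test_confusion_counts_pool_to_n(self):
        matrix = gaussian_matrix(n_pos=20, n_neg=25, separation=1.0, seed=3)
        result = evaluate(matrix, CVConfig(k=5, seed=0))
        for tp, fn, tn, fp in result.confusion.values():
            assert tp + fn == 20
            assert tn + fp == 25

    def test_macc_invariant_to_classifier_order(self):
        matrix = gaussian_matrix(n_pos=15, n_neg=15, separation=2.0, seed=5)
        forward = evaluate(matrix, CVConfig(k=3, seed=0))
        names = tuple(reversed(forward.per_classifier_accuracy))
        backward = evaluate(matrix, CVConfig(k=3, seed=0, classifiers=names))
        assert forward.mAcc == backward.mAcc
        assert forward.per_classifier_accuracy == pytest.approx(
            backward.per_classifier_accuracy)

    def test_null_labels_near_chance(self):
        # label-permuted data: accuracy within 3 binomial SDs of the
        # majority-class rate
        rng = np.random.default_rng(7)
        n = 60
        X = rng.standard_normal((n, 5))
        y = np.array([0] * 30 + [1] * 30)
        rng.shuffle(y)
        ids = [f"i{i}" for i in range(n)]
        matrix = FeatureMatrix(ids, [f"f{i}" for i in range(5)], X,
                               class_labels=y)
        result = evaluate(matrix, CVConfig(k=5, seed=0))
        sd = np.sqrt(0.5 * 0.5 / n)
        for acc in result.per_classifier_accuracy.values():
            assert abs(acc - 0.5) <= 3 * sd + 0.1

    def test_non_binary_labels_rejected(self):
        matrix = gaussian_matrix(n_pos=10, n_neg=10)
        matrix.class_labels = np.arange(20)
        with pytest.raises(ValueError, match="binary"):
            evaluate(matrix, CVConfig(k=2))


class TestMetrics:
    def test_macc_is_maximum(self):
        result = CVResult(
            per_classifier_accuracy={"SVM": 0.9, "NN": 0.8, "LR": 0.95},
            confusion={n: (1, 0, 1, 0) for n in ("SVM", "NN", "LR")})
        assert result.mAcc == 0.95
        assert result.best_classifier == "LR"

    def test_sensitivity_specificity_ratios(self):
        result = CVResult(per_classifier_accuracy={"SVM": 0.875},
                          confusion={"SVM": (3, 1, 4, 0)})
        assert result.sensitivity["SVM"] == pytest.approx(0.75)
        assert result.specificity["SVM"] == pytest.approx(1.0)


class TestHoldout:
    def test_proportional_counts(self):
        matrix = gaussian_matrix(n_pos=40, n_neg=60, seed=1)
        train, test = holdout_split(matrix, train_fraction=0.7, seed=0)
        assert int(np.sum(train.class_labels == 1)) == 28
        assert int(np.sum(train.class_labels == 0)) == 42
        assert train.shape[0] + test.shape[0] == 100

    def test_deterministic_given_seed(self):
        matrix = gaussian_matrix(n_pos=12, n_neg=12, seed=2)
        a_train, a_test = holdout_split(matrix, seed=4)
        b_train, b_test = holdout_split(matrix, seed=4)
        assert a_train.image_ids == b_train.image_ids
        assert a_test.image_ids == b_test.image_ids

    def test_degenerate_fraction_rejected(self):
        matrix = gaussian_matrix(n_pos=5, n_neg=5, seed=2)
        with pytest.raises(ValueError):
            holdout_split(matrix, train_fraction=0.999, seed=0)

    def test_separable_holdout_perfect_sensitivity_specificity(self):
        matrix = gaussian_matrix(seed=11)
        train, test = holdout_split(matrix, 0.7, seed=0)
        result = evaluate_holdout(train, test, CVConfig(k=2, seed=0))
        best = result.best_classifier
        assert result.sensitivity[best] == 1.0
        assert result.specificity[best] == 1.0
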
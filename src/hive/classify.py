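"""Multi-classifier evaluation of a feature matrix under stratified k-fold CV.

The protocol: for each classifier in the panel, train on k-1 folds and
predict the held-out fold, pooling predictions over all folds; accuracy is
the pooled fraction of correctly predicted images.  The headline summary
mAcc is the maximum of the per-classifier accuracies.  Confusion counts are
pooled the same way, with sensitivity = TP / (TP + FN) and specificity =
TN / (TN + FP) for the positive and negative class respectively.

The panel holds six classifiers — support vector machine (SVM), nearest
neighbor (NN), decision tree (DTree), naive Bayes (NBayes), logistic
regression (LR) and random forest (RF) — with library-default
hyperparameters; all randomness (fold shuffling, stochastic classifiers)
derives from one user-supplied seed.  This module owns the evaluation
protocol and metric arithmetic; classifier training delegates to
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import FeatureMatrix

CLASSIFIER_NAMES = ("SVM", "NN", "DTree", "NBayes", "LR", "RF")


def make_classifier(name: str, seed: int):
    """A fresh sklearn estimator for one panel member."""
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "NN":
        return KNeighborsClassifier()
    if name == "DTree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "NBayes":
        return GaussianNB()
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


@dataclass
class CVConfig:
    """Cross-validation protocol settings."""

    k: int = 10
    seed: int = 0
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        unknown = [c for c in self.classifiers if c not in CLASSIFIER_NAMES]
        if unknown:
            raise ValueError(f"unknown classifiers {unknown}")


@dataclass
class CVResult:
    """Pooled cross-validation outcome for one feature matrix."""

    per_classifier_accuracy: dict[str, float]
    confusion: dict[str, tuple[int, int, int, int]]  # (TP, FN, TN, FP)
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (tp, fn, tn, fp) in self.confusion.items():
            self.sensitivity.setdefault(
                name, tp / (tp + fn) if tp + fn else float("nan"))
            self.specificity.setdefault(
                name, tn / (tn + fp) if tn + fp else float("nan"))

    @property
    def mAcc(self) -> float:
        return max(self.per_classifier_accuracy.values())

    @property
    def best_classifier(self) -> str:
        return max(self.per_classifier_accuracy,
                   key=self.per_classifier_accuracy.get)

    def to_dict(self) -> dict:
        return {
            "per_classifier_accuracy": self.per_classifier_accuracy,
            "mAcc": self.mAcc,
            "best_classifier": self.best_classifier,
            "confusion": {k: list(v) for k, v in self.confusion.items()},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must be binary 0/1; got classes {classes}")
    return y


def stratified_folds(class_labels, k: int, seed: int) -> np.ndarray:
    """Fold index (0..k-1) per sample, class-balanced within <= 1 sample.

    Each class must have at least k members so every fold sees both classes.
    """
    y = _check_binary(class_labels)
    for cls in (0, 1):
        if np.sum(y == cls) < k:
            raise ValueError(
                f"class {cls} has fewer than k={k} members; stratified "
                f"{k}-fold assignment is impossible"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = fold
    return folds


def _pooled_confusion(y_true: np.ndarray, y_pred: np.ndarray):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return tp, fn, tn, fp


def evaluate(matrix: FeatureMatrix, config: CVConfig | None = None) -> CVResult:
    """Pooled stratified k-fold evaluation of the classifier panel."""
    config = config or CVConfig()
    if matrix.class_labels is None:
        raise ValueError("matrix carries no class labels")
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    y = _check_binary(matrix.class_labels)
    folds = stratified_folds(y, config.k, config.seed)

    accuracies: dict[str, float] = {}
    confusion: dict[str, tuple[int, int, int, int]] = {}
    for name in config.classifiers:
        pred = np.empty_like(y)
        for fold in range(config.k):
            test = folds == fold
            clf = make_classifier(name, config.seed)
            clf.fit(X[~test], y[~test])
            pred[test] = clf.predict(X[test])
        accuracies[name] = float(np.mean(pred == y))
        confusion[name] = _pooled_confusion(y, pred)
    return CVResult(per_classifier_accuracy=accuracies, confusion=confusion)


def holdout_split(matrix: FeatureMatrix, train_fraction: float = 0.7,
                  seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random train/test split preserving class proportions."""
    if matrix.class_labels is None:
        raise ValueError("matrix carries no class labels")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = _check_binary(matrix.class_labels)
    idx = np.arange(len(y))
    try:
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, stratify=y, random_state=seed)
    except ValueError as exc:
        raise ValueError(f"train_fraction={train_fraction} leaves an "
                         f"unusable split: {exc}") from exc

    def subset(indices) -> FeatureMatrix:
        indices = np.sort(indices)
        return FeatureMatrix(
            image_ids=[matrix.image_ids[i] for i in indices],
            labels=list(matrix.labels),
            values=matrix.values[indices],
            class_labels=y[indices],
        )

    return subset(train_idx), subset(test_idx)


def evaluate_holdout(train: FeatureMatrix, test: FeatureMatrix,
                     config: CVConfig | None = None) -> CVResult:
    """Train each panel member on *train* and score on *test*."""
    config = config or CVConfig()
    y_train = _check_binary(train.class_labels)
    y_test = _check_binary(test.class_labels)
    accuracies: dict[str, float] = {}
    confusion: dict[str, tuple[int, int, int, int]] = {}
    for name in config.classifiers:
        clf = make_classifier(name, config.seed)
        clf.fit(train.values, y_train)
        pred = clf.predict(test.values)
        accuracies[name] = float(np.mean(pred == y_test))
        confusion[name] = _pooled_confusion(y_test, pred)
    return CVResult(per_classifier_accuracy=accuracies, confusion=confusion)
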
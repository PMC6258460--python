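"""Feature post-processing: merge, z-score normalization, PCA reduction.

Per-algorithm feature vectors are merged column-wise in the fixed order HOG,
LBP, GLCM, HEM, CAN with rows sorted by image id.  Normalization is a
z-score with the population standard deviation (the different descriptors
live on wildly different scales, which is the whole reason the step exists);
zero-variance columns become all-zero rather than NaN.  PCA mean-centers
(without scaling — scaling is the separate normalize step), keeps
``min(n_rows, n_cols)`` components by default, and fixes each axis's sign so
its largest-magnitude loading is positive, making serialized outputs
byte-reproducible.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .records import ALGORITHM_ORDER, FeatureMatrix, FeatureVector


def merge(vectors: list[FeatureVector], class_labels=None) -> FeatureMatrix:
    """Merge per-image, per-algorithm vectors into one FeatureMatrix.

    Every image must carry a vector for every algorithm present, and lengths
    must agree per algorithm across images; violations raise with the
    offending images named.
    """
    if not vectors:
        raise ValueError("no feature vectors to merge")
    algorithms = [a for a in ALGORITHM_ORDER
                  if any(v.algorithm == a for v in vectors)]
    image_ids = sorted({v.image_id for v in vectors})
    by_key = {(v.image_id, v.algorithm): v for v in vectors}

    missing = [(iid, alg) for iid in image_ids for alg in algorithms
               if (iid, alg) not in by_key]
    if missing:
        raise ValueError(f"missing (image, algorithm) vectors: {missing}")

    for alg in algorithms:
        lengths = {iid: len(by_key[(iid, alg)]) for iid in image_ids}
        counts = Counter(lengths.values())
        expected = counts.most_common(1)[0][0]
        bad = [iid for iid, n in lengths.items() if n != expected]
        if bad:
            raise ValueError(
                f"{alg} vector length mismatch for images {bad} "
                f"(expected {expected})"
            )

    labels: list[str] = []
    for alg in algorithms:
        labels.extend(by_key[(image_ids[0], alg)].labels)
    rows = [
        np.concatenate([by_key[(iid, alg)].values for alg in algorithms])
        for iid in image_ids
    ]
    if class_labels is not None:
        class_labels = np.asarray([class_labels[iid] for iid in image_ids])
    return FeatureMatrix(image_ids=image_ids, labels=labels,
                         values=np.vstack(rows), class_labels=class_labels)


class FeatureNormalizer(TransformerMixin, BaseEstimator):
    """Column z-score with population SD; constant columns map to zero."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("normalization needs at least 2 rows")
        self.scaler_ = StandardScaler().fit(X)  # ddof=0; zero-var scale_ -> 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scaler_")
        return self.scaler_.transform(np.asarray(X, dtype=np.float64))


class PCAReducer(TransformerMixin, BaseEstimator):
    """Mean-centering PCA with deterministic component signs.

    Parameters
    ----------
    n_components : int or None, default None
        Number of principal axes; None keeps ``min(n_rows, n_cols)``.

    Attributes
    ----------
    components_ : ndarray (k, n_features)
        Principal axes, sign-fixed so each row's largest-|loading| entry is
        positive.
    explained_variance_ : ndarray (k,)
        Sample variances along each axis, non-increasing.
    mean_ : ndarray (n_features,)
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, m = X.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 rows")
        k = min(n, m) if self.n_components is None else int(self.n_components)
        if not 1 <= k <= min(n, m):
            raise ValueError(
                f"n_components={k} must lie in [1, min(n_rows, n_cols)="
                f"{min(n, m)}]"
            )
        pca = PCA(n_components=k, svd_solver="full").fit(X)
        components = pca.components_
        # deterministic signs: largest-|loading| coordinate positive
        flip = np.sign(
            components[np.arange(k), np.argmax(np.abs(components), axis=1)]
        )
        flip[flip == 0] = 1.0
        self.components_ = components * flip[:, None]
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) @ self.components_.T


def _relabeled(matrix: FeatureMatrix, values: np.ndarray, labels) -> FeatureMatrix:
    return FeatureMatrix(image_ids=list(matrix.image_ids), labels=list(labels),
                         values=values, class_labels=matrix.class_labels)


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score every column of *matrix* (population SD; see module docs)."""
    values = FeatureNormalizer().fit_transform(matrix.values)
    return _relabeled(matrix, values, matrix.labels)


def pca_reduce(matrix: FeatureMatrix, n_components: int | None = None) -> FeatureMatrix:
    """Project *matrix* onto its principal axes; columns become PC1..PCk."""
    reducer = PCAReducer(n_components=n_components)
    scores = reducer.fit_transform(matrix.values)
    labels = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return _relabeled(matrix, scores, labels)
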
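"""Shared scaffolding for the descriptor transformers.

Every extractor is a stateless scikit-learn transformer: ``fit`` only
validates parameters, ``transform`` maps a batch of grayscale images to a
2-D feature array, and ``get_feature_names_out`` yields the algorithm-prefixed
column labels.  Extractors therefore compose directly with sklearn pipelines
and with the batch orchestrator.
"""

from __future__ import annotations

from abc import abstractmethod

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .records import FeatureVector, ImageRecord


def as_pixel_grid(image) -> np.ndarray:
    """Accept an ImageRecord or a bare 2-D array of ``[0, 1]`` intensities."""
    if isinstance(image, ImageRecord):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale pixel grid")
    return arr


class ImageFeatureExtractor(TransformerMixin, BaseEstimator):
    """Base class: batch of images in, ``(n_images, n_features)`` array out."""

    #: Short algorithm tag used as the feature-label prefix.
    algorithm: str = ""

    def fit(self, X, y=None):
        self._validate_params()
        return self

    def transform(self, X) -> np.ndarray:
        self._validate_params()
        grids = [as_pixel_grid(img) for img in X]
        if grids:
            self._input_shape = grids[0].shape
        rows = [self._extract(g) for g in grids]
        if not rows:
            return np.empty((0, 0))
        lengths = {r.size for r in rows}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.algorithm}: images produced differing feature lengths "
                f"{sorted(lengths)}; resize inputs to a common target size"
            )
        return np.vstack(rows)

    def extract(self, image) -> FeatureVector:
        """Compute this extractor's FeatureVector for a single image."""
        self._validate_params()
        pixels = as_pixel_grid(image)
        values = self._extract(pixels)
        image_id = image.image_id if isinstance(image, ImageRecord) else ""
        return FeatureVector(
            image_id=image_id,
            algorithm=self.algorithm,
            values=values,
            labels=list(self.feature_labels(pixels.shape)),
        )

    def feature_labels(self, shape: tuple[int, int]) -> list[str]:
        """Column labels for an image of the given (rows, cols) shape."""
        n = self.n_features(shape)
        return [f"{self.algorithm}_{i}" for i in range(n)]

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "_input_shape"):
            raise ValueError("call transform first or pass feature_labels a shape")
        return np.asarray(self.feature_labels(self._input_shape), dtype=object)

    def _validate_params(self) -> None:  # noqa: B027 - optional hook
        pass

    @abstractmethod
    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        """Flattened descriptor for one pixel grid."""

    @abstractmethod
    def n_features(self, shape: tuple[int, int]) -> int:
        """Output length for an image of the given shape."""
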
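"""Core in-memory containers shared by every stage of the pipeline.

An :class:`ImageRecord` is a single grayscale image with intensities in
``[0, 1]``; a :class:`FeatureVector` is one extractor's flat output for one
image; a :class:`FeatureMatrix` is the merged images x features table that the
writers serialize.  All three are plain dataclasses over numpy arrays — the
heavy lifting lives in the extractor transformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed extractor ordering used when merging per-algorithm blocks.
ALGORITHM_ORDER = ("HOG", "LBP", "GLCM", "HEM", "CAN")


@dataclass
class ImageRecord:
    """A loaded grayscale image.

    Parameters
    ----------
    image_id : str
        Source filename without directory; unique within one run.
    pixels : ndarray of shape (n_rows, n_cols)
        Grayscale intensities in ``[0, 1]``, row-major, origin top-left.
    source_path : str
        Where the image was read from ("" for synthetic images).
    """

    image_id: str
    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid with n, m >= 1")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("intensities must lie in [0, 1]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FeatureVector:
    """One extractor's flattened output for one image."""

    image_id: str
    algorithm: str
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.algorithm not in ALGORITHM_ORDER:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.labels:
            self.labels = [f"{self.algorithm}_{i}" for i in range(self.values.size)]
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for image {self.image_id!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FeatureMatrix:
    """Merged feature table: rows are images, columns are labeled features."""

    image_ids: list[str]
    labels: list[str]
    values: np.ndarray
    class_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(self.image_ids), len(self.labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.image_ids)} ids x {len(self.labels)} labels"
            )
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("duplicated image_id")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicated feature label")
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels)
            if self.class_labels.shape != (len(self.image_ids),):
                raise ValueError("class_labels length must equal row count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame indexed by image_id."""
        frame = pd.DataFrame(self.values, index=self.image_ids, columns=self.labels)
        frame.index.name = "image_id"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, class_labels=None) -> "FeatureMatrix":
        return cls(
            image_ids=[str(i) for i in frame.index],
            labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=np.float64),
            class_labels=class_labels,
        )
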
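"""Gray-level co-occurrence matrices and Haralick-style texture properties.

The co-occurrence matrix counts ordered pairs of quantized gray levels at a
fixed pixel offset.  Angles use matrix (row, col) coordinates with 90 deg
pointing up (negative row):

======  ============
angle   offset (d=1)
======  ============
0       (0, +1)
45      (-1, +1)
90      (-1, 0)
135     (-1, -1)
======  ============

Six scalar properties are derived per (distance, angle) slice: contrast,
dissimilarity, homogeneity, ASM, energy and correlation.  Correlation of a
slice with zero marginal variance (e.g. a constant image) is defined as 1 so
degenerate images stay finite.
"""

from __future__ import annotations

import logging

import numpy as np

from .base import ImageFeatureExtractor

logger = logging.getLogger(__name__)

PROPERTIES = ("contrast", "dissimilarity", "homogeneity", "energy",
              "correlation", "ASM")

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize_levels(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin ``[0, 1]`` intensities into integer levels 0..levels-1."""
    lev = np.floor(np.asarray(pixels, dtype=np.float64) * levels).astype(np.int64)
    return np.minimum(lev, levels - 1)


def compute_glcm(
    image,
    levels: int = 256,
    distances=(1,),
    angles=(0, 45, 90, 135),
    symmetric: bool = True,
    normed: bool = True,
) -> np.ndarray:
    """Co-occurrence array of shape ``(levels, levels, n_dist, n_angle)``.

    Pairs whose second endpoint falls outside the image are not counted; a
    slice whose offset exceeds the image size is all-zero (logged, not
    fatal).  When *symmetric*, each slice gains its transpose; when *normed*,
    each slice is divided by its own total.
    """
    from .base import as_pixel_grid

    if not 2 <= levels <= 256:
        raise ValueError("levels must lie in [2, 256]")
    if any(int(d) < 1 for d in distances):
        raise ValueError("every distance must be >= 1")
    if any(a not in _ANGLE_OFFSETS for a in angles):
        raise ValueError(f"angles must come from {sorted(_ANGLE_OFFSETS)}")
    pixels = as_pixel_grid(image)
    q = quantize_levels(pixels, levels)
    n, m = q.shape
    out = np.zeros((levels, levels, len(distances), len(angles)))
    for di, d in enumerate(distances):
        for ai, angle in enumerate(angles):
            dr, dc = (v * int(d) for v in _ANGLE_OFFSETS[angle])
            if abs(dr) >= n or abs(dc) >= m:
                logger.warning(
                    "offset d=%s angle=%s exceeds image %s; slice left zero",
                    d, angle, q.shape,
                )
                continue
            r0, r1 = max(0, -dr), min(n, n - dr)
            c0, c1 = max(0, -dc), min(m, m - dc)
            src = q[r0:r1, c0:c1].ravel()
            dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
            slice_ = np.zeros((levels, levels))
            np.add.at(slice_, (src, dst), 1.0)
            if symmetric:
                slice_ = slice_ + slice_.T
            if normed:
                total = slice_.sum()
                if total > 0:
                    slice_ = slice_ / total
            out[:, :, di, ai] = slice_
    return out


def haralick_properties(glcm: np.ndarray, properties=PROPERTIES) -> np.ndarray:
    """Scalar texture statistics of normalized co-occurrence slices.

    Returns a flat vector ordered property-major, then distance, then angle.
    """
    unknown = [p for p in properties if p not in PROPERTIES]
    if unknown:
        raise ValueError(f"unknown GLCM properties: {unknown}")
    levels, _, n_dist, n_angle = glcm.shape
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    out = np.empty((len(properties), n_dist, n_angle))
    for di in range(n_dist):
        for ai in range(n_angle):
            P = glcm[:, :, di, ai]
            asm = float(np.sum(P**2))
            values = {}
            values["contrast"] = float(np.sum(P * (i - j) ** 2))
            values["dissimilarity"] = float(np.sum(P * np.abs(i - j)))
            values["homogeneity"] = float(np.sum(P / (1.0 + (i - j) ** 2)))
            values["ASM"] = asm
            values["energy"] = float(np.sqrt(asm))
            pi = P.sum(axis=1)
            pj = P.sum(axis=0)
            mu_i = float(np.sum(i.ravel() * pi))
            mu_j = float(np.sum(j.ravel() * pj))
            var_i = float(np.sum((i.ravel() - mu_i) ** 2 * pi))
            var_j = float(np.sum((j.ravel() - mu_j) ** 2 * pj))
            denom = np.sqrt(var_i * var_j)
            if denom == 0.0:
                values["correlation"] = 1.0  # degenerate slice convention
            else:
                cov = float(np.sum(P * (i - mu_i) * (j - mu_j)))
                values["correlation"] = cov / denom
            for pk, prop in enumerate(properties):
                out[pk, di, ai] = values[prop]
    return out.ravel()


class GLCMExtractor(ImageFeatureExtractor):
    """Haralick texture-property transformer over co-occurrence matrices.

    The feature output is the property values (not the raw ``levels^2``
    matrices, which would dwarf every other descriptor); the raw array
    remains available through :func:`compute_glcm`.

    Parameters
    ----------
    levels : int, default 256
        Gray levels after uniform quantization of ``[0, 1]``.
    distances : sequence of int, default (1,)
    angles : sequence from {0, 45, 90, 135}, default all four
    symmetric, normed : bool, default True
    properties : sequence, default all six
    """

    algorithm = "GLCM"

    def __init__(self, levels: int = 256, distances=(1,),
                 angles=(0, 45, 90, 135), symmetric: bool = True,
                 normed: bool = True, properties=PROPERTIES):
        self.levels = levels
        self.distances = distances
        self.angles = angles
        self.symmetric = symmetric
        self.normed = normed
        self.properties = properties

    def _validate_params(self) -> None:
        if not 2 <= self.levels <= 256:
            raise ValueError("levels must lie in [2, 256]")
        unknown = [p for p in self.properties if p not in PROPERTIES]
        if unknown:
            raise ValueError(f"unknown GLCM properties: {unknown}")

    def n_features(self, shape: tuple[int, int]) -> int:
        return len(self.properties) * len(self.distances) * len(self.angles)

    def feature_labels(self, shape: tuple[int, int]) -> list[str]:
        return [
            f"GLCM_{prop}_d{d}_a{a}"
            for prop in self.properties
            for d in self.distances
            for a in self.angles
        ]

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        glcm = compute_glcm(
            pixels, levels=self.levels, distances=self.distances,
            angles=self.angles, symmetric=self.symmetric, normed=self.normed,
        )
        return haralick_properties(glcm, self.properties)
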
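"""Canny edge detection: smoothing, gradient, NMS, hysteresis.

Stages: (i) Gaussian smoothing with reflect padding; (ii) gradient magnitude
and orientation from central differences; (iii) non-maximum suppression with
the gradient direction quantized into four sectors (0, 45, 90, 135 degrees),
where a pixel survives iff its magnitude is ``>=`` both neighbors along the
sector — the ``>=`` tie-break keeps deterministic one-pixel ridges on
plateaus; (iv) double-threshold hysteresis: pixels at or above the high
threshold seed edges, and surviving pixels at or above the low threshold are
kept iff 8-connected to a seed.

Thresholds live on the gradient-magnitude scale of a ``[0, 1]`` image; with
``use_quantiles=True`` they are instead read as quantiles of the nonzero
gradient magnitudes, which is more robust across image types.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .base import ImageFeatureExtractor
from .hog import compute_gradients

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def nonmax_suppression(magnitude: np.ndarray, orientation: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels that are local maxima along the gradient.

    *orientation* is in degrees ``[0, 180)``; it is quantized to the nearest
    of the four sectors and each pixel is compared (``>=``) against its two
    discrete neighbors along that sector.  Out-of-bounds neighbors count as
    zero magnitude.
    """
    sector = np.mod(np.rint(orientation / 45.0).astype(int), 4)
    padded = np.pad(magnitude, 1, mode="constant")
    n, m = magnitude.shape
    view = lambda dr, dc: padded[1 + dr : 1 + dr + n, 1 + dc : 1 + dc + m]
    # neighbor pairs along the gradient direction, per sector; orientation is
    # atan2(gr, gc) with rows growing downward, so 45 deg is the main
    # diagonal (down-right) and 135 deg the anti-diagonal (down-left)
    pairs = {
        0: ((0, 1), (0, -1)),
        1: ((1, 1), (-1, -1)),
        2: ((-1, 0), (1, 0)),
        3: ((1, -1), (-1, 1)),
    }
    keep = np.zeros_like(magnitude, dtype=bool)
    for s, ((dr1, dc1), (dr2, dc2)) in pairs.items():
        mask = sector == s
        keep |= mask & (magnitude >= view(dr1, dc1)) & (magnitude >= view(dr2, dc2))
    return keep & (magnitude > 0)


def hysteresis(magnitude: np.ndarray, nms: np.ndarray, low: float, high: float):
    """Keep weak (>= low) NMS survivors 8-connected to a strong (>= high) seed."""
    weak = nms & (magnitude >= low)
    strong = nms & (magnitude >= high)
    labels, _ = ndimage.label(weak, structure=_EIGHT_CONN)
    seeded = np.unique(labels[strong])
    return np.isin(labels, seeded[seeded > 0])


class CannyExtractor(ImageFeatureExtractor):
    """Canny edge-map transformer: binary {0, 1} map, one value per pixel.

    Parameters
    ----------
    sigma : float, default 1.0
        Gaussian smoothing scale.
    low_threshold, high_threshold : float, defaults 0.1 and 0.2
        Hysteresis thresholds, ``0 <= low <= high``.
    use_quantiles : bool, default False
        Interpret thresholds as quantiles of the nonzero gradient magnitudes.
    """

    algorithm = "CAN"

    def __init__(self, sigma: float = 1.0, low_threshold: float = 0.1,
                 high_threshold: float = 0.2, use_quantiles: bool = False):
        self.sigma = sigma
        self.low_threshold = low_threshold
        self.high_threshold = high_threshold
        self.use_quantiles = use_quantiles

    def _validate_params(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.low_threshold <= self.high_threshold:
            raise ValueError("need 0 <= low_threshold <= high_threshold")
        if self.use_quantiles and self.high_threshold > 1:
            raise ValueError("quantile thresholds must lie in [0, 1]")

    def n_features(self, shape: tuple[int, int]) -> int:
        return shape[0] * shape[1]

    def edge_map(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean edge map with full pipeline semantics (2-D, unflattened)."""
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim != 2 or min(pixels.shape) < 3:
            raise ValueError("Canny needs a grid of at least 3x3")
        smoothed = ndimage.gaussian_filter(
            pixels, self.sigma, mode="reflect", truncate=4.0
        )
        magnitude, orientation = compute_gradients(smoothed, signed=False)
        nms = nonmax_suppression(magnitude, orientation)
        low, high = self.low_threshold, self.high_threshold
        if self.use_quantiles:
            nonzero = magnitude[magnitude > 0]
            if nonzero.size == 0:
                return np.zeros_like(nms)
            low = float(np.quantile(nonzero, low))
            high = float(np.quantile(nonzero, high))
        return hysteresis(magnitude, nms, low, high)

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        return self.edge_map(pixels).ravel().astype(np.float64)


def compute_canny(image, sigma: float = 1.0, low_threshold: float = 0.1,
                  high_threshold: float = 0.2, use_quantiles: bool = False):
    """Functional wrapper: Canny FeatureVector of one image."""
    return CannyExtractor(
        sigma=sigma, low_threshold=low_threshold,
        high_threshold=high_threshold, use_quantiles=use_quantiles,
    ).extract(image)
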
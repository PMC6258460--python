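"""Local Binary Pattern code images.

For every pixel, ``P`` neighbors are sampled on a circle of radius ``R``
(bilinear interpolation for off-lattice positions, edge-replicated padding at
the borders) and thresholded against the center with a ``>=`` comparison, so
ties — including constant images — set the bit.  The default output is the
flattened code image, one code per pixel: a 352 x 240 image yields
``352 * 240 = 84,480`` features.

Variants collapse equivalent codes: ``rotation_invariant`` takes the minimum
over all cyclic bit rotations; ``uniform`` maps codes with more than two
0/1 transitions to the single label ``P + 1`` and uniform codes to their
popcount; ``rotation_invariant_uniform`` composes both (uniform codes keep
their popcount, which is already rotation invariant).
"""

from __future__ import annotations

import numpy as np

from .base import ImageFeatureExtractor
from .image_io import quantize_8bit

VARIANTS = ("default", "rotation_invariant", "uniform", "rotation_invariant_uniform")

# >= comparisons tolerate this much float error on the 0..255 quantized scale,
# so bilinear weights that sum to 1 only up to rounding cannot flip a tie bit
_TIE_EPS = 1e-7


def circle_offsets(n_points: int, radius: float) -> np.ndarray:
    """(dr, dc) sampling offsets; k=0 along +columns, counter-clockwise.

    Counter-clockwise in image coordinates means decreasing row for the
    first quadrant, hence ``dr = -R sin`` and ``dc = R cos``.  Near-integer
    components are snapped so axis-aligned neighbors are sampled exactly.
    """
    angles = 2.0 * np.pi * np.arange(n_points) / n_points
    offsets = np.stack([-radius * np.sin(angles), radius * np.cos(angles)], axis=1)
    snapped = np.rint(offsets)
    near = np.abs(offsets - snapped) < 1e-9
    offsets[near] = snapped[near]
    return offsets


def _sample_bilinear(padded: np.ndarray, rows, cols) -> np.ndarray:
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    return (
        padded[r0, c0] * (1 - fr) * (1 - fc)
        + padded[r0, c0 + 1] * (1 - fr) * fc
        + padded[r0 + 1, c0] * fr * (1 - fc)
        + padded[r0 + 1, c0 + 1] * fr * fc
    )


def rotation_invariant_code(code: int, n_points: int) -> int:
    """Minimum of *code* over all cyclic rotations of its P-bit pattern."""
    mask = (1 << n_points) - 1
    best = code
    for shift in range(1, n_points):
        rotated = ((code >> shift) | (code << (n_points - shift))) & mask
        best = min(best, rotated)
    return best


def uniform_code(code: int, n_points: int) -> int:
    """Popcount for uniform patterns (<= 2 transitions), else ``P + 1``."""
    bits = [(code >> k) & 1 for k in range(n_points)]
    transitions = sum(bits[k] != bits[(k + 1) % n_points] for k in range(n_points))
    if transitions <= 2:
        return sum(bits)
    return n_points + 1


class LBPExtractor(ImageFeatureExtractor):
    """Local Binary Pattern transformer emitting per-pixel code images.

    Parameters
    ----------
    n_points : int, default 8
        Neighbors sampled on the circle (P >= 4).
    radius : float, default 1.0
        Circle radius in pixels.
    variant : {"default", "rotation_invariant", "uniform",
        "rotation_invariant_uniform"}, default "default"
    """

    algorithm = "LBP"

    def __init__(self, n_points: int = 8, radius: float = 1.0,
                 variant: str = "default"):
        self.n_points = n_points
        self.radius = radius
        self.variant = variant

    def _validate_params(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def n_features(self, shape: tuple[int, int]) -> int:
        return shape[0] * shape[1]

    def _code_table(self) -> np.ndarray | None:
        """Variant lookup table over all raw codes (None for default)."""
        if self.variant == "default":
            return None
        raw = np.arange(2**self.n_points)
        if self.variant == "rotation_invariant":
            mapped = [rotation_invariant_code(c, self.n_points) for c in raw]
        elif self.variant == "uniform":
            mapped = [uniform_code(c, self.n_points) for c in raw]
        else:  # rotation_invariant_uniform
            mapped = [
                uniform_code(rotation_invariant_code(c, self.n_points), self.n_points)
                for c in raw
            ]
        return np.asarray(mapped, dtype=np.int64)

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        n, m = pixels.shape
        if min(n, m) < 2 * self.radius + 1:
            raise ValueError(
                f"image {pixels.shape} smaller than the sampling circle "
                f"(needs at least {2 * self.radius + 1} pixels per side)"
            )
        levels = quantize_8bit(pixels).astype(np.float64)
        pad = int(np.ceil(self.radius)) + 1
        padded = np.pad(levels, pad, mode="edge")
        rows = np.arange(n)[:, None] + pad
        cols = np.arange(m)[None, :] + pad
        codes = np.zeros((n, m), dtype=np.int64)
        for k, (dr, dc) in enumerate(circle_offsets(self.n_points, self.radius)):
            neighbor = _sample_bilinear(padded, rows + dr, cols + dc)
            bit = neighbor - levels >= -_TIE_EPS
            codes |= bit.astype(np.int64) << k
        table = self._code_table()
        if table is not None:
            codes = table[codes]
        return codes.ravel().astype(np.float64)


def compute_lbp(image, n_points: int = 8, radius: float = 1.0,
                variant: str = "default"):
    """Functional wrapper: LBP FeatureVector of one image."""
    return LBPExtractor(n_points=n_points, radius=radius,
                        variant=variant).extract(image)
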
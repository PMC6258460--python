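"""Histogram of Oriented Gradients, implemented from first principles.

The descriptor follows the canonical construction: centered ``(-1, 0, +1)``
intensity gradients, magnitude-weighted orientation histograms over square
pixel cells with bilinear voting between the two nearest orientation bins,
and contrast normalization over overlapping blocks of cells.

With the defaults (9 unsigned orientation bins, 8x8-pixel cells, 3x3-cell
blocks stepped one cell at a time, L2-Hys block normalization) a
352 x 240 image yields ``42 * 28 * 3 * 3 * 9 = 95,256`` features: 44 x 30
complete cells give 42 x 28 block positions, each block contributing nine
9-bin cell histograms.
"""

from __future__ import annotations

import numpy as np

from .base import ImageFeatureExtractor

_EPS = 1e-12


def compute_gradients(
    pixels: np.ndarray, signed: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and orientation in degrees.

    Central differences with the ``(-1, 0, +1)`` kernel in the interior and
    one-sided differences on the borders.  Orientation is ``atan2(gr, gc)``
    mapped to ``[0, 360)`` when *signed*, else folded to ``[0, 180)``.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise ValueError("gradient computation needs a grid of at least 3x3")
    gr = np.empty_like(pixels)
    gc = np.empty_like(pixels)
    gr[1:-1, :] = (pixels[2:, :] - pixels[:-2, :]) / 2.0
    gr[0, :] = pixels[1, :] - pixels[0, :]
    gr[-1, :] = pixels[-1, :] - pixels[-2, :]
    gc[:, 1:-1] = (pixels[:, 2:] - pixels[:, :-2]) / 2.0
    gc[:, 0] = pixels[:, 1] - pixels[:, 0]
    gc[:, -1] = pixels[:, -1] - pixels[:, -2]
    magnitude = np.hypot(gr, gc)
    orientation = np.degrees(np.arctan2(gr, gc))  # 0 deg = +column direction
    if signed:
        orientation = np.mod(orientation, 360.0)
    else:
        orientation = np.mod(orientation, 180.0)
    return magnitude, orientation


def cell_histograms(
    magnitude: np.ndarray,
    orientation: np.ndarray,
    cell_size: int,
    orientations: int,
    signed: bool = False,
) -> np.ndarray:
    """Magnitude-weighted orientation histograms over complete cells.

    Votes are split linearly between the two orientation bins whose centers
    bracket each pixel's orientation (circular interpolation), so the total
    histogram mass of a cell equals the sum of its pixels' gradient
    magnitudes exactly.

    Returns an array of shape ``(n_cells_r, n_cells_c, orientations)``.
    """
    span = 360.0 if signed else 180.0
    bin_width = span / orientations
    n_cells_r = magnitude.shape[0] // cell_size
    n_cells_c = magnitude.shape[1] // cell_size
    # trim incomplete trailing cells
    mag = magnitude[: n_cells_r * cell_size, : n_cells_c * cell_size]
    ori = orientation[: n_cells_r * cell_size, : n_cells_c * cell_size]

    # bin centers at (k + 0.5) * bin_width; circular linear interpolation
    pos = ori / bin_width - 0.5
    lo = np.floor(pos).astype(np.int64)
    w_hi = pos - lo
    lo_bin = np.mod(lo, orientations)
    hi_bin = np.mod(lo + 1, orientations)

    hist = np.zeros((n_cells_r, n_cells_c, orientations))
    cell_r = np.arange(mag.shape[0]) // cell_size
    cell_c = np.arange(mag.shape[1]) // cell_size
    rr = np.broadcast_to(cell_r[:, None], mag.shape).ravel()
    cc = np.broadcast_to(cell_c[None, :], mag.shape).ravel()
    np.add.at(hist, (rr, cc, lo_bin.ravel()), (mag * (1.0 - w_hi)).ravel())
    np.add.at(hist, (rr, cc, hi_bin.ravel()), (mag * w_hi).ravel())
    return hist


def _normalize_block(block: np.ndarray, norm: str) -> np.ndarray:
    out = block / np.sqrt(np.sum(block**2) + _EPS**2)
    if norm == "L2-Hys":
        out = np.minimum(out, 0.2)
        out = out / np.sqrt(np.sum(out**2) + _EPS**2)
    return out


class HOGExtractor(ImageFeatureExtractor):
    """Histogram of Oriented Gradients transformer.

    Parameters
    ----------
    orientations : int, default 9
        Number of orientation histogram bins.
    cell_size : int, default 8
        Pixels per cell side.
    block_size : int, default 3
        Cells per block side.
    block_stride : int, default 1
        Step between block positions, in cells.
    signed_gradients : bool, default False
        When False, orientations are folded to ``[0, 180)``.
    block_norm : {"L2", "L2-Hys"}, default "L2-Hys"
        Per-block contrast normalization; L2-Hys clips at 0.2 and
        renormalizes.
    """

    algorithm = "HOG"

    def __init__(
        self,
        orientations: int = 9,
        cell_size: int = 8,
        block_size: int = 3,
        block_stride: int = 1,
        signed_gradients: bool = False,
        block_norm: str = "L2-Hys",
    ):
        self.orientations = orientations
        self.cell_size = cell_size
        self.block_size = block_size
        self.block_stride = block_stride
        self.signed_gradients = signed_gradients
        self.block_norm = block_norm

    def _validate_params(self) -> None:
        for name in ("orientations", "cell_size", "block_size", "block_stride"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.block_norm not in ("L2", "L2-Hys"):
            raise ValueError("block_norm must be 'L2' or 'L2-Hys'")

    def _block_grid(self, shape: tuple[int, int]) -> tuple[int, int]:
        n_cells_r = shape[0] // self.cell_size
        n_cells_c = shape[1] // self.cell_size
        if n_cells_r < self.block_size or n_cells_c < self.block_size:
            minimum = self.block_size * self.cell_size
            raise ValueError(
                f"image {shape} too small for one {self.block_size}x"
                f"{self.block_size}-cell block; needs at least "
                f"{minimum}x{minimum} pixels"
            )
        nbr = (n_cells_r - self.block_size) // self.block_stride + 1
        nbc = (n_cells_c - self.block_size) // self.block_stride + 1
        return nbr, nbc

    def n_features(self, shape: tuple[int, int]) -> int:
        nbr, nbc = self._block_grid(shape)
        return nbr * nbc * self.block_size**2 * self.orientations

    def _extract(self, pixels: np.ndarray) -> np.ndarray:
        nbr, nbc = self._block_grid(pixels.shape)
        magnitude, orientation = compute_gradients(pixels, self.signed_gradients)
        hist = cell_histograms(
            magnitude, orientation, self.cell_size, self.orientations,
            self.signed_gradients,
        )
        bs, stride = self.block_size, self.block_stride
        out = np.empty((nbr, nbc, bs * bs * self.orientations))
        for i in range(nbr):
            for j in range(nbc):
                block = hist[
                    i * stride : i * stride + bs, j * stride : j * stride + bs
                ].ravel()
                out[i, j] = _normalize_block(block, self.block_norm)
        return out.ravel()


def compute_hog(image, orientations=9, cell_size=8, block_size=3,
                block_stride=1, signed_gradients=False, block_norm="L2-Hys"):
    """Functional wrapper: HOG FeatureVector of one image."""
    return HOGExtractor(
        orientations=orientations, cell_size=cell_size, block_size=block_size,
        block_stride=block_stride, signed_gradients=signed_gradients,
        block_norm=block_norm,
    ).extract(image)
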
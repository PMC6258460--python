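"""Image loading: directory scans, raster decoding, grayscale conversion, resize.

All images enter the pipeline as :class:`~hive.records.ImageRecord` objects
with float intensities in ``[0, 1]``.  Multi-channel inputs are collapsed with
ITU-R BT.709 luminance weights; resizing uses plain bilinear interpolation
(no anti-aliasing prefilter) so results are simple to reason about and
bit-reproducible across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .records import ImageRecord

logger = logging.getLogger(__name__)

#: Extensions accepted by the directory scanner (case-insensitive).
RASTER_EXTENSIONS = frozenset(
    {".bmp", ".gif", ".jpg", ".jpeg", ".png", ".ppm", ".pgm", ".pbm",
     ".tif", ".tiff", ".webp"}
)

#: BT.709 luminance weights (R, G, B).
BT709_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class ConfigurationError(ValueError):
    """A fatal problem with user-supplied configuration or inputs."""


def list_images(directory: str | Path) -> list[Path]:
    """List recognized raster files in *directory*, sorted by filename.

    Non-image files are skipped with a logged warning.  Raises
    :class:`ConfigurationError` if the directory is missing or holds no
    recognized images, since a batch run without inputs is a setup mistake.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigurationError(f"input directory does not exist: {directory}")
    images, skipped = [], []
    for entry in directory.iterdir():
        if not entry.is_file():
            continue
        if entry.suffix.lower() in RASTER_EXTENSIONS:
            images.append(entry)
        else:
            skipped.append(entry.name)
    for name in sorted(skipped):
        logger.warning("skipping non-image file: %s", name)
    if not images:
        raise ConfigurationError(f"no images found in {directory}")
    return sorted(images, key=lambda p: p.name)


def to_grayscale(rgb_pixels: np.ndarray) -> np.ndarray:
    """Collapse a 3- or 4-channel ``[0, 1]`` image to BT.709 luminance.

    A trailing alpha channel is dropped; a single-channel input passes
    through unchanged.
    """
    pixels = np.asarray(rgb_pixels, dtype=np.float64)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim != 3 or pixels.shape[2] not in (1, 3, 4):
        raise ValueError(
            f"expected 1, 3 or 4 channels, got shape {pixels.shape}"
        )
    if pixels.shape[2] == 1:
        return pixels[:, :, 0]
    return pixels[:, :, :3] @ BT709_WEIGHTS


def load_image(path: str | Path) -> ImageRecord:
    """Decode one raster file into a grayscale ``[0, 1]`` record.

    Raises on unreadable files; the batch layer catches this and skips the
    file so a single corrupt image cannot abort a run over hundreds.
    """
    path = Path(path)
    with Image.open(path) as img:
        img.load()
        if img.mode not in ("L", "I", "I;16", "F", "RGB", "RGBA"):
            img = img.convert("RGBA" if "A" in img.mode else "RGB")
        arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr / 255.0
        pixels = to_grayscale(arr)
    else:
        # 8-bit L, 16-bit I and float modes each carry their own full scale
        if img.mode in ("I", "I;16"):
            arr = arr / 65535.0
        elif img.mode != "F":
            arr = arr / 255.0
        pixels = arr
    return ImageRecord(image_id=path.name, pixels=np.clip(pixels, 0.0, 1.0),
                       source_path=str(path))


def resize(image: ImageRecord, target_width: int, target_height: int) -> ImageRecord:
    """Bilinearly resample *image* to exactly target_height x target_width."""
    if target_width < 1 or target_height < 1:
        raise ConfigurationError("resize target dimensions must be >= 1")
    n, m = image.shape
    if (target_height, target_width) == (n, m):
        return image
    out = _bilinear_resize(image.pixels, target_height, target_width)
    return ImageRecord(image.image_id, np.clip(out, 0.0, 1.0), image.source_path)


def _bilinear_resize(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear interpolation with pixel-center alignment."""
    in_h, in_w = pixels.shape
    # map output pixel centers into input pixel-center coordinates
    r = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    c = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    r = np.clip(r, 0, in_h - 1)
    c = np.clip(c, 0, in_w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, in_h - 1)
    c1 = np.minimum(c0 + 1, in_w - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    top = pixels[r0][:, c0] * (1 - fc) + pixels[r0][:, c1] * fc
    bot = pixels[r1][:, c0] * (1 - fc) + pixels[r1][:, c1] * fc
    return top * (1 - fr) + bot * fr


def quantize_8bit(pixels: np.ndarray) -> np.ndarray:
    """Round ``[0, 1]`` intensities to integer 8-bit levels 0..255."""
    return np.rint(np.asarray(pixels, dtype=np.float64) * 255.0).astype(np.int64)
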
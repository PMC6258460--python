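"""Deterministic synthetic images and labeled texture datasets.

Every module in the package is testable without external data thanks to
these generators.  Simple patterns (constant, ramp, step edge, checkerboard,
seeded Gaussian noise) exercise the analytic corner cases of the extractors;
the two texture classes — seeded white noise smoothed by strongly
anisotropic Gaussian filters at two different orientations — produce a
linearly separable binary problem for exactly the descriptors the pipeline
computes (orientation structure for HOG, co-occurrence structure for GLCM),
standing in for real two-class texture collections.

Identical specs always yield byte-identical images: all randomness flows
through a seeded generator and nothing depends on wall clock or filesystem
ordering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .records import ImageRecord

KINDS = ("constant", "ramp", "step_edge", "checkerboard", "gaussian_noise",
         "textured_class_A", "textured_class_B")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image."""

    kind: str
    width: int = 64
    height: int = 64
    seed: int = 0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.width < 1 or self.height < 1:
            raise ValueError("dimensions must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")


def _oriented_texture(height: int, width: int, seed: int, axis: int) -> np.ndarray:
    """White noise smoothed hard along one axis: an oriented stripe texture."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    sigma = (0.5, 6.0) if axis == 0 else (6.0, 0.5)
    tex = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    lo, hi = tex.min(), tex.max()
    if hi - lo < 1e-12:
        return np.full_like(tex, 0.5)
    return (tex - lo) / (hi - lo)


def make_image(spec: FixtureSpec) -> ImageRecord:
    """Render one synthetic image; identical specs give identical pixels."""
    h, w, a = spec.height, spec.width, spec.amplitude
    if spec.kind == "constant":
        pixels = np.full((h, w), a)
    elif spec.kind == "ramp":
        cols = np.arange(w) / max(w - 1, 1)
        pixels = np.broadcast_to(cols * a, (h, w)).copy()
    elif spec.kind == "step_edge":
        pixels = np.zeros((h, w))
        pixels[:, w // 2 :] = a
    elif spec.kind == "checkerboard":
        r = np.arange(h)[:, None] // 8
        c = np.arange(w)[None, :] // 8
        pixels = ((r + c) % 2) * a
    elif spec.kind == "gaussian_noise":
        rng = np.random.default_rng(spec.seed)
        pixels = np.clip(0.5 + 0.15 * rng.standard_normal((h, w)), 0, 1) * a
    elif spec.kind == "textured_class_A":
        pixels = _oriented_texture(h, w, spec.seed, axis=0) * a
    else:  # textured_class_B
        pixels = _oriented_texture(h, w, spec.seed, axis=1) * a
    image_id = f"{spec.kind}_{spec.seed}_{w}x{h}.png"
    return ImageRecord(image_id=image_id, pixels=pixels)


def save_png(record: ImageRecord, path: str | Path) -> Path:
    """Write an ImageRecord as an 8-bit grayscale PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    eight_bit = np.rint(record.pixels * 255.0).astype(np.uint8)
    Image.fromarray(eight_bit, mode="L").save(path, format="PNG")
    return path


def make_labeled_set(n_per_class: int, width: int = 256, height: int = 256,
                     seed: int = 0, out_dir: str | Path = "images") -> Path:
    """Write a two-class texture dataset: PNGs plus a labels CSV.

    Class A images (label 1) carry horizontally-oriented texture, class B
    (label 0) vertically-oriented; n_per_class of each.  Returns the path of
    the labels file (``labels.csv`` inside *out_dir*).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_per_class):
        for kind, label in (("textured_class_A", 1), ("textured_class_B", 0)):
            spec = FixtureSpec(kind=kind, width=width, height=height,
                               seed=seed * 100_000 + 2 * i + label)
            record = make_image(spec)
            name = f"{kind[-1]}_{i:03d}.png"
            save_png(record, out_dir / name)
            rows.append((name, label))
    labels_path = out_dir / "labels.csv"
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class"])
        writer.writerows(sorted(rows))
    return labels_path


def load_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (image_id, class) labels CSV."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["image_id"]] = int(row["class"])
    return labels
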
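"""Config-driven batch engine: scan, extract in parallel, merge, serialize.

One "processor" task handles one image file: load, optional resize to the
configured target size, then one feature vector per selected algorithm.
Tasks are pure functions of (file bytes, config), so they may run on any
worker; results are keyed by image id and assembled in lexicographic order
regardless of completion order, which makes the serialized outputs
byte-identical for every ``njob`` setting.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path

from .base import ImageFeatureExtractor
from .canny import CannyExtractor
from .config import PipelineConfig
from .glcm import GLCMExtractor
from .hessian import HessianExtractor
from .hog import HOGExtractor
from .image_io import ConfigurationError, list_images, load_image, resize
from .lbp import LBPExtractor
from .postprocess import merge, normalize, pca_reduce
from .records import FeatureMatrix, FeatureVector
from .writers import FORMAT_EXTENSIONS, write_matrix

logger = logging.getLogger(__name__)


def build_extractors(config: PipelineConfig) -> dict[str, ImageFeatureExtractor]:
    """Instantiate the selected extractors with their config parameters."""
    factories = {
        "HOG": (HOGExtractor, config.hog),
        "LBP": (LBPExtractor, config.lbp),
        "GLCM": (GLCMExtractor, config.glcm),
        "HEM": (HessianExtractor, config.hessian),
        "CAN": (CannyExtractor, config.canny),
    }
    return {
        name: cls(**params)
        for name, (cls, params) in factories.items()
        if name in config.algorithms
    }


def process_image(path: str | Path, config: PipelineConfig) -> list[FeatureVector]:
    """Run all selected extractors on one file; empty list on decode failure."""
    try:
        record = load_image(path)
    except Exception as exc:  # decode errors must not kill the batch
        logger.warning("skipping unreadable image %s: %s", path, exc)
        return []
    if config.target_size is not None:
        width, height = config.target_size
        record = resize(record, width, height)
    return [ext.extract(record) for ext in build_extractors(config).values()]


def run(config: PipelineConfig) -> FeatureMatrix:
    """Execute one batch run; returns the merged (post-processed) matrix.

    Dispatches one processor task per image over up to ``njob`` workers,
    merges in sorted image-id order, applies the optional normalize and PCA
    steps (in that order), and writes the matrix once per requested format
    into ``output_dir`` as ``features.<ext>``.
    """
    paths = list_images(config.input_dir)
    logger.info("processing %d images with algorithms %s (njob=%d)",
                len(paths), config.algorithms, config.njob)

    if config.njob == 1:
        results = [process_image(p, config) for p in paths]
    else:
        with ProcessPoolExecutor(max_workers=config.njob) as pool:
            results = list(pool.map(process_image, paths,
                                    [config] * len(paths), chunksize=1))

    vectors = [v for res in results for v in res]
    n_ok = sum(1 for res in results if res)
    logger.info("extracted features from %d/%d images", n_ok, len(paths))
    if not vectors:
        raise ConfigurationError("all input images were unreadable")

    matrix = merge(vectors)
    for alg in config.algorithms:
        n_feat = sum(1 for lbl in matrix.labels if lbl.startswith(alg))
        logger.info("%s: %d features per image", alg, n_feat)

    if config.keep_intermediate:
        _write_intermediates(vectors, config)
    if config.normalize:
        matrix = normalize(matrix)
    if config.pca:
        matrix = pca_reduce(matrix, config.pca_components)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for fmt in config.output_formats:
        dest = out_dir / f"features{FORMAT_EXTENSIONS[fmt]}"
        write_matrix(matrix, fmt, config.decimals, dest)
        logger.info("wrote %s", dest)
    return matrix


def _write_intermediates(vectors: list[FeatureVector], config: PipelineConfig) -> None:
    """Optional per-image feature files (one CSV per image) before merging."""
    inter_dir = Path(config.output_dir) / "per_image"
    inter_dir.mkdir(parents=True, exist_ok=True)
    by_image: dict[str, list[FeatureVector]] = {}
    for v in vectors:
        by_image.setdefault(v.image_id, []).append(v)
    for image_id, vecs in by_image.items():
        matrix = merge(vecs)
        stem = Path(image_id).stem
        write_matrix(matrix, "CSV", config.decimals, inter_dir / f"{stem}.csv")


def plot_feature_histogram(vector: FeatureVector, bins: int,
                           destination: str | Path):
    """Save a histogram of one feature vector's values as a PNG.

    Returns the bin counts, which always sum to the vector length.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(vector) == 0:
        raise ValueError("cannot plot a histogram of an empty feature vector")
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, _, _ = ax.hist(vector.values, bins=bins)
    ax.set_xlabel(f"{vector.algorithm} feature value")
    ax.set_ylabel("count")
    ax.set_title(f"{vector.algorithm} features of {vector.image_id}")
    fig.tight_layout()
    fig.savefig(destination, format="png")
    plt.close(fig)
    return counts
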
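"""INI configuration parsing for the batch pipeline.

Sections: ``[general]``, ``[hog]``, ``[lbp]``, ``[glcm]``, ``[hessian]``,
``[canny]``, ``[postprocess]``, ``[output]``.  Every key is optional and
falls back to a documented default; unknown keys are ignored with a warning
while malformed values are fatal, naming the key and the expected type.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .image_io import ConfigurationError
from .records import ALGORITHM_ORDER

logger = logging.getLogger(__name__)

OUTPUT_FORMATS = ("CSV", "PICKLE", "JSON", "EXCEL", "TXT", "SQL")


@dataclass
class PipelineConfig:
    """Full description of one batch run."""

    input_dir: str = "images"
    output_dir: str = "features"
    algorithms: tuple[str, ...] = ALGORITHM_ORDER
    njob: int = 1
    target_size: tuple[int, int] | None = None  # (width, height)
    normalize: bool = False
    pca: bool = False
    pca_components: int | None = None  # None = "auto"
    output_formats: tuple[str, ...] = ("CSV",)
    decimals: int = 6
    keep_intermediate: bool = False
    hog: dict = field(default_factory=dict)
    lbp: dict = field(default_factory=dict)
    glcm: dict = field(default_factory=dict)
    hessian: dict = field(default_factory=dict)
    canny: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.algorithms = tuple(
            a for a in ALGORITHM_ORDER if a in {x.upper() for x in self.algorithms}
        )
        if not self.algorithms:
            raise ConfigurationError("algorithms must be non-empty")
        self.output_formats = tuple(
            f.upper() for f in self.output_formats
        )
        bad = [f for f in self.output_formats if f not in OUTPUT_FORMATS]
        if bad:
            raise ConfigurationError(
                f"unknown output formats {bad}; choose from {OUTPUT_FORMATS}"
            )
        if not self.output_formats:
            raise ConfigurationError("output_formats must be non-empty")
        if self.njob < 1:
            raise ConfigurationError("njob must be >= 1")
        if self.decimals < 0:
            raise ConfigurationError("decimals must be >= 0")
        if self.target_size is not None:
            w, h = self.target_size
            if w < 1 or h < 1:
                raise ConfigurationError("target_size dimensions must be >= 1")


_KNOWN_KEYS = {
    "general": {"input_dir", "output_dir", "algorithms", "njob", "target_size"},
    "hog": {"orientations", "cell_size", "block_size", "block_stride",
            "signed_gradients", "block_norm"},
    "lbp": {"n_points", "radius", "variant"},
    "glcm": {"levels", "distances", "angles", "symmetric", "normed", "properties"},
    "hessian": {"sigma", "output"},
    "canny": {"sigma", "low_threshold", "high_threshold", "use_quantiles"},
    "postprocess": {"normalize", "pca", "pca_components"},
    "output": {"formats", "decimals", "keep_intermediate"},
}

_BOOL = {"true": True, "1": True, "yes": True, "on": True,
         "false": False, "0": False, "no": False, "off": False}


def _convert(section: str, key: str, raw: str, kind: str):
    try:
        if kind == "int":
            return int(raw)
        if kind == "float":
            return float(raw)
        if kind == "bool":
            return _BOOL[raw.strip().lower()]
        if kind == "int_list":
            return tuple(int(x) for x in raw.replace(",", " ").split())
        if kind == "str_list":
            return tuple(x for x in raw.replace(",", " ").split())
        return raw.strip()
    except (ValueError, KeyError):
        raise ConfigurationError(
            f"[{section}] {key} = {raw!r}: expected {kind}"
        ) from None


def parse_config(path: str | Path | None = None) -> PipelineConfig:
    """Parse an INI config file; a missing path yields all defaults."""
    parser = configparser.ConfigParser()
    if path is not None:
        path = Path(path)
        if not path.is_file():
            raise ConfigurationError(f"configuration file not found: {path}")
        parser.read(path)

    values: dict = {}
    algo_params: dict[str, dict] = {s: {} for s in
                                    ("hog", "lbp", "glcm", "hessian", "canny")}

    for section in parser.sections():
        sec = section.lower()
        if sec not in _KNOWN_KEYS:
            logger.warning("ignoring unknown config section [%s]", section)
            continue
        for key, raw in parser.items(section):
            if key not in _KNOWN_KEYS[sec]:
                logger.warning("ignoring unknown key [%s] %s", section, key)
                continue
            _assign(values, algo_params, sec, key, raw)

    return PipelineConfig(**values, **algo_params)


def _assign(values: dict, algo_params: dict, sec: str, key: str, raw: str) -> None:
    if sec == "general":
        if key in ("input_dir", "output_dir"):
            values[key] = raw.strip()
        elif key == "algorithms":
            values["algorithms"] = _convert(sec, key, raw, "str_list")
        elif key == "njob":
            values["njob"] = _convert(sec, key, raw, "int")
        elif key == "target_size":
            pair = _convert(sec, key, raw.lower().replace("x", " "), "int_list")
            if len(pair) != 2:
                raise ConfigurationError(
                    f"[general] target_size = {raw!r}: expected WIDTHxHEIGHT"
                )
            values["target_size"] = pair
    elif sec == "postprocess":
        if key in ("normalize", "pca"):
            values[key] = _convert(sec, key, raw, "bool")
        elif key == "pca_components":
            values["pca_components"] = (
                None if raw.strip().lower() == "auto"
                else _convert(sec, key, raw, "int")
            )
    elif sec == "output":
        if key == "formats":
            values["output_formats"] = _convert(sec, key, raw, "str_list")
        elif key == "decimals":
            values["decimals"] = _convert(sec, key, raw, "int")
        elif key == "keep_intermediate":
            values["keep_intermediate"] = _convert(sec, key, raw, "bool")
    else:  # extractor parameter blocks
        kinds = {
            ("hog", "orientations"): "int", ("hog", "cell_size"): "int",
            ("hog", "block_size"): "int", ("hog", "block_stride"): "int",
            ("hog", "signed_gradients"): "bool", ("hog", "block_norm"): "str",
            ("lbp", "n_points"): "int", ("lbp", "radius"): "float",
            ("lbp", "variant"): "str",
            ("glcm", "levels"): "int", ("glcm", "distances"): "int_list",
            ("glcm", "angles"): "int_list", ("glcm", "symmetric"): "bool",
            ("glcm", "normed"): "bool", ("glcm", "properties"): "str_list",
            ("hessian", "sigma"): "float", ("hessian", "output"): "str",
            ("canny", "sigma"): "float", ("canny", "low_threshold"): "float",
            ("canny", "high_threshold"): "float",
            ("canny", "use_quantiles"): "bool",
        }
        algo_params[sec][key] = _convert(sec, key, raw, kinds[(sec, key)])
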
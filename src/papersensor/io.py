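"""Image and config I/O plus run manifests.

Images travel as lossless 8-bit RGB PNG or TIFF; 16-bit TIFF input is
rescaled to 8 bits by integer division by 257 (full-range 65535 → 255).
JPEG is refused by default — the pipeline's quality contracts are made on
lossless images — and must be opted into with ``allow_lossy=True``.

Every CLI run writes a ``manifest.json`` with the resolved configuration,
its SHA-256 hash, the seed, and library versions: two runs with equal
manifests produce equal outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ConfigError",
    "UnsupportedFormatError",
    "ImageReadError",
    "RunConfig",
    "load_config",
    "read_image",
    "write_image",
    "write_run_manifest",
]

logger = logging.getLogger(__name__)

_LOSSLESS_FORMATS = {"PNG", "TIFF"}
_SUFFIXES = {".png": "PNG", ".tif": "TIFF", ".tiff": "TIFF"}

SUBCOMMANDS = ("generate", "degrade", "detect", "classify", "sweep")

# Allowed (and required) config keys per subcommand.
_SCHEMAS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "generate": (
        frozenset({"out"}),
        frozenset(
            {
                "width", "height", "resolution", "n_particles", "mixture", "min_gap_px",
                "background_mean", "background_sigma",
            }
        ),
    ),
    "degrade": (frozenset({"in", "out"}), frozenset({"gaussian", "blur", "wb", "allow_lossy"})),
    "detect": (
        frozenset({"in", "out"}),
        frozenset({"px_per_cm", "frame_cm", "frame_px", "params", "allow_lossy", "csv"}),
    ),
    "classify": (frozenset({"density"}), frozenset()),
    "sweep": (
        frozenset({"out"}),
        frozenset({"particle_counts", "n_seeds", "width", "height", "families", "min_gap_px"}),
    ),
}

_GLOBAL_KEYS = frozenset({"subcommand", "seed", "log_level"})


class ConfigError(ValueError):
    """A config file violates the documented schema."""


class UnsupportedFormatError(ValueError):
    """Image format outside the lossless PNG/TIFF contract."""


class ImageReadError(OSError):
    """The image file could not be decoded."""


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration for one CLI subcommand."""

    subcommand: str
    seed: int = 0
    log_level: str = "INFO"
    options: Mapping[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config.

    The file must name exactly one ``subcommand`` and may set ``seed`` and
    ``log_level``; all other keys must belong to that subcommand's schema.
    Unknown keys and missing required keys raise :class:`ConfigError`
    naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of keys to values")
    sub = raw.get("subcommand")
    if sub not in SUBCOMMANDS:
        raise ConfigError(
            f"config must set 'subcommand' to one of {', '.join(SUBCOMMANDS)}; got {sub!r}"
        )
    required, optional = _SCHEMAS[sub]
    allowed = required | optional | _GLOBAL_KEYS
    for key in raw:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' for subcommand '{sub}'")
    for key in required:
        if key not in raw:
            raise ConfigError(f"missing required key '{key}' for subcommand '{sub}'")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"'seed' must be an integer, got {seed!r}")
    options = {k: v for k, v in raw.items() if k not in _GLOBAL_KEYS}
    return RunConfig(
        subcommand=sub, seed=seed, log_level=str(raw.get("log_level", "INFO")), options=options
    )


def read_image(path: str | Path, allow_lossy: bool = False) -> np.ndarray:
    """Read an image as an 8-bit RGB array of shape (height, width, 3).

    PNG and TIFF are accepted; 16-bit TIFF is converted to 8-bit by
    ``value // 257``.  JPEG (and any other lossy format) raises
    :class:`UnsupportedFormatError` unless ``allow_lossy`` is set.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            fmt = im.format
            if fmt not in _LOSSLESS_FORMATS and not (allow_lossy and fmt == "JPEG"):
                raise UnsupportedFormatError(
                    f"{path.name}: format {fmt} not supported; use lossless PNG/TIFF "
                    "(JPEG only behind allow_lossy)"
                )
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise ImageReadError(f"cannot decode {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype == np.int32:  # PIL mode "I" (32-bit TIFF) — treat as 16-bit range
        arr = (np.clip(arr, 0, 65535) // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise UnsupportedFormatError(f"{path.name}: unsupported pixel type {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit image losslessly; the format follows the suffix."""
    path = Path(path)
    fmt = _SUFFIXES.get(path.suffix.lower())
    if fmt is None:
        raise UnsupportedFormatError(f"unsupported image suffix '{path.suffix}' (use PNG/TIFF)")
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected a uint8 image, got {arr.dtype}")
    Image.fromarray(arr).save(path, format=fmt)


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_run_manifest(out_dir: str | Path, config: Mapping[str, Any], seed: int) -> Path:
    """Write manifest.json capturing config, its hash, seed, and versions."""
    import scipy
    import PIL

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "coordinate_convention": "0-based (row, column), origin top-left",
        "config": dict(config),
        "config_sha256": _config_hash(config),
        "seed": seed,
        "versions": {
            "papersensor": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pillow": PIL.__version__,
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return path
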
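"""Synthetic paper-sensor image generation with exact per-particle ground truth.

A DiY paper air sensor is a 6 cm × 6 cm white square coated with petroleum
jelly; airborne particles stick to it as dark dots and the sheet is then
photographed.  Field photographs with annotated particle counts are scarce,
so this module synthesizes them: a near-white textured background with
anti-aliased dark disks of known diameter (µm), grey level, and PM class,
placed uniformly at random with a configurable minimum edge-to-edge gap.

At the working scale of 1 px/µm a full 6 cm frame would be 60,000 px wide;
images are therefore sub-frame crops, and the physical crop area in cm²
(``SensorImageSpec.area_cm2``) is what dot-density pollution ratings use.

Everything is reproducible bit-for-bit from the image spec, the particle
list and an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import PMClass, pm_class

if TYPE_CHECKING:  # pragma: no cover
    from .degrade import DegradationConfig

__all__ = [
    "SensorImageSpec",
    "ParticleGT",
    "GroundTruth",
    "GridCell",
    "PlacementInfeasibleError",
    "OutOfBoundsParticleError",
    "InvalidMixtureError",
    "DIAMETER_STRATA_UM",
    "DEFAULT_MIXTURE",
    "PM10_ONLY_MIXTURE",
    "sample_particles",
    "render_sensor_image",
    "generate_dataset",
]


class PlacementInfeasibleError(RuntimeError):
    """Requested particle density cannot be placed at the requested gap."""


class OutOfBoundsParticleError(ValueError):
    """A particle center lies outside the image."""


class InvalidMixtureError(ValueError):
    """PM-class mixture weights are negative or all zero."""


#: Disjoint diameter strata (lo, hi], µm, sampled uniformly within each class.
DIAMETER_STRATA_UM: dict[PMClass, tuple[float, float]] = {
    PMClass.PM1: (0.0, 1.0),
    PMClass.PM2_5: (1.0, 2.5),
    PMClass.PM10: (2.5, 10.0),
}

#: Default "diverse mixture": equal weight on PM1 / PM2.5 / PM10.
DEFAULT_MIXTURE: tuple[float, float, float] = (1.0, 1.0, 1.0)

#: Mixture for experiments that count a pre-known quantity of PM10 particles.
PM10_ONLY_MIXTURE: tuple[float, float, float] = (0.0, 0.0, 1.0)

_MIXTURE_ORDER: tuple[PMClass, ...] = (PMClass.PM1, PMClass.PM2_5, PMClass.PM10)

#: Grey levels of rendered dots are drawn uniformly from [0, _GREY_MAX].
_GREY_MAX = 120

# Random close packing of disks stalls well below full coverage; beyond this
# fill fraction rejection sampling is declared infeasible up front.
_PACKING_LIMIT = 0.55

_ATTEMPTS_PER_PARTICLE = 200


@dataclass(frozen=True)
class SensorImageSpec:
    """Geometry, resolution and background of a synthetic sensor image.

    Parameters
    ----------
    width_px, height_px : int
        Image dimensions in pixels (≥ 16 each).
    resolution_px_per_um : float
        Working resolution; 1 px/µm matches the detection pipeline's target.
    frame_size_cm : float
        Physical size of the (square) full sensor frame.  Images are crops;
        this is metadata for calibration, not the rendered extent.
    background_mean : int
        Mean grey level of the white paper, in [200, 255].
    background_sigma : float
        Std.\\ dev.\\ of iid Gaussian paper-texture jitter (DN), ≥ 0.
    """

    width_px: int = 2000
    height_px: int = 2000
    resolution_px_per_um: float = 1.0
    frame_size_cm: float = 6.0
    background_mean: int = 245
    background_sigma: float = 2.0

    #: All images are 8-bit.
    BIT_DEPTH = 8

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ValueError("width_px and height_px must be >= 16")
        if not (self.resolution_px_per_um > 0 and math.isfinite(self.resolution_px_per_um)):
            raise ValueError("resolution_px_per_um must be positive and finite")
        if not (self.frame_size_cm > 0 and math.isfinite(self.frame_size_cm)):
            raise ValueError("frame_size_cm must be positive and finite")
        if not 200 <= self.background_mean <= 255:
            raise ValueError("background_mean must be in [200, 255] (white paper)")
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be non-negative")

    @property
    def width_cm(self) -> float:
        """Physical width of the imaged crop in cm."""
        return self.width_px / (self.resolution_px_per_um * 1e4)

    @property
    def height_cm(self) -> float:
        return self.height_px / (self.resolution_px_per_um * 1e4)

    @property
    def area_cm2(self) -> float:
        """Physical crop area in cm² (drives the dust-scale density)."""
        return (self.width_px * self.height_px) / (self.resolution_px_per_um**2 * 1e8)

    @property
    def px_per_cm(self) -> float:
        return self.resolution_px_per_um * 1e4


@dataclass(frozen=True)
class ParticleGT:
    """Ground truth for one rendered particle.

    Coordinates are 0-based (column = x, row = y), origin at the top-left
    pixel center.  ``diameter_um`` is the true disk diameter; ``pm_class``
    is consistent with it under :func:`papersensor.classify.pm_class`.
    """

    id: int
    center_x_px: float
    center_y_px: float
    diameter_um: float
    grey_level: int
    pm_class: PMClass

    def __post_init__(self) -> None:
        if not 0.0 < self.diameter_um <= 10.0:
            raise ValueError(f"diameter_um must be in (0, 10], got {self.diameter_um}")
        if not 0 <= self.grey_level <= 255:
            raise ValueError("grey_level must be in [0, 255]")
        if pm_class(self.diameter_um) is not self.pm_class:
            raise ValueError(
                f"pm_class {self.pm_class} inconsistent with diameter {self.diameter_um} um"
            )


@dataclass(frozen=True)
class GroundTruth:
    """A particle list plus the image spec and seed that produced it."""

    particles: tuple[ParticleGT, ...]
    spec: SensorImageSpec
    seed: int

    @property
    def n_total(self) -> int:
        return len(self.particles)

    @property
    def n_by_class(self) -> dict[PMClass, int]:
        counts = {c: 0 for c in PMClass}
        for p in self.particles:
            counts[p.pm_class] += 1
        return counts

    def to_records(self) -> list[dict]:
        return [
            {
                "id": p.id,
                "center_x_px": p.center_x_px,
                "center_y_px": p.center_y_px,
                "diameter_um": p.diameter_um,
                "grey_level": p.grey_level,
                "pm_class": p.pm_class.value,
            }
            for p in self.particles
        ]

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["id", "center_x_px", "center_y_px", "diameter_um", "grey_level", "pm_class"]
        return pd.DataFrame(self.to_records(), columns=cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coordinate_convention": "0-based (row, column), origin top-left",
            "seed": self.seed,
            "spec": dataclasses.asdict(self.spec),
            "n_total": self.n_total,
            "n_by_class": {c.value: n for c, n in self.n_by_class.items()},
            "particles": self.to_records(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        spec = SensorImageSpec(**payload["spec"])
        particles = tuple(
            ParticleGT(
                id=r["id"],
                center_x_px=r["center_x_px"],
                center_y_px=r["center_y_px"],
                diameter_um=r["diameter_um"],
                grey_level=r["grey_level"],
                pm_class=PMClass(r["pm_class"]),
            )
            for r in payload["particles"]
        )
        return cls(particles=particles, spec=spec, seed=payload["seed"])


def _normalize_mixture(
    mixture: Sequence[float] | Mapping[PMClass | str, float] | None,
) -> np.ndarray:
    """Return mixture weights as probabilities over (PM1, PM2.5, PM10)."""
    if mixture is None:
        w = np.asarray(DEFAULT_MIXTURE, dtype=float)
    elif isinstance(mixture, Mapping):
        w = np.array([float(mixture.get(c, mixture.get(c.value, 0.0))) for c in _MIXTURE_ORDER])
    else:
        w = np.asarray(list(mixture), dtype=float)
        if w.shape != (3,):
            raise InvalidMixtureError("mixture must have three weights (PM1, PM2.5, PM10)")
    if np.any(w < 0):
        raise InvalidMixtureError(f"mixture weights must be non-negative, got {w.tolist()}")
    total = w.sum()
    if total <= 0:
        raise InvalidMixtureError("mixture weights must not all be zero")
    return w / total


def sample_particles(
    spec: SensorImageSpec,
    n: int,
    mixture: Sequence[float] | Mapping[PMClass | str, float] | None = None,
    min_gap_px: float = 1.0,
    seed: int = 0,
) -> list[ParticleGT]:
    """Draw ``n`` particles with random class, diameter, grey level and position.

    Classes are drawn from ``mixture`` (weights over PM1/PM2.5/PM10, default
    uniform); diameters are uniform within each class stratum (PM1 (0,1],
    PM2.5 (1,2.5], PM10 (2.5,10] µm); grey levels uniform integers in
    [0, 120]; centers uniform over the interior such that every disk lies
    fully inside the image and, when ``min_gap_px > 0``, all pairwise
    edge-to-edge separations are at least ``min_gap_px``.

    Raises
    ------
    PlacementInfeasibleError
        If the requested density cannot be placed (area bound exceeded, or
        rejection sampling exhausts its attempt budget).
    InvalidMixtureError
        For negative or all-zero mixture weights.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if min_gap_px < 0:
        raise ValueError("min_gap_px must be non-negative")
    weights = _normalize_mixture(mixture)
    rng = np.random.default_rng(seed)
    if n == 0:
        return []

    cls_idx = rng.choice(3, size=n, p=weights)
    lo = np.array([DIAMETER_STRATA_UM[c][0] for c in _MIXTURE_ORDER])
    hi = np.array([DIAMETER_STRATA_UM[c][1] for c in _MIXTURE_ORDER])
    # hi - (hi-lo)*U[0,1) is uniform on (lo, hi]: keeps PM1 diameters > 0.
    diameters = hi[cls_idx] - (hi[cls_idx] - lo[cls_idx]) * rng.random(n)
    greys = rng.integers(0, _GREY_MAX + 1, size=n)

    radii_px = diameters * spec.resolution_px_per_um / 2.0
    margin = radii_px + 1.0  # keep the full disk (plus AA skirt) inside
    usable_w = spec.width_px - 2 * margin
    usable_h = spec.height_px - 2 * margin
    if np.any(usable_w <= 0) or np.any(usable_h <= 0):
        raise PlacementInfeasibleError("image too small for the largest requested particle")

    if min_gap_px > 0:
        fill = float(np.sum(np.pi * (radii_px + min_gap_px / 2.0) ** 2))
        if fill > _PACKING_LIMIT * spec.width_px * spec.height_px:
            raise PlacementInfeasibleError(
                f"requested density infeasible: {n} particles would fill "
                f"{fill / (spec.width_px * spec.height_px):.0%} of the image "
                f"at min_gap_px={min_gap_px}"
            )

    xs = np.empty(n)
    ys = np.empty(n)
    if min_gap_px == 0:
        xs[:] = margin + rng.random(n) * usable_w
        ys[:] = margin + rng.random(n) * usable_h
    else:
        r_max = float(radii_px.max())
        cell = 2.0 * r_max + min_gap_px
        grid: dict[tuple[int, int], list[int]] = {}
        for i in range(n):
            placed = False
            for _ in range(_ATTEMPTS_PER_PARTICLE):
                x = margin[i] + rng.random() * usable_w[i]
                y = margin[i] + rng.random() * usable_h[i]
                cx, cy = int(x // cell), int(y // cell)
                ok = True
                for gx in range(cx - 1, cx + 2):
                    for gy in range(cy - 1, cy + 2):
                        for j in grid.get((gx, gy), ()):
                            dx = x - xs[j]
                            dy = y - ys[j]
                            limit = radii_px[i] + radii_px[j] + min_gap_px
                            if dx * dx + dy * dy < limit * limit:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if ok:
                    xs[i], ys[i] = x, y
                    grid.setdefault((cx, cy), []).append(i)
                    placed = True
                    break
            if not placed:
                raise PlacementInfeasibleError(
                    f"could not place particle {i + 1}/{n} after "
                    f"{_ATTEMPTS_PER_PARTICLE} attempts (min_gap_px={min_gap_px})"
                )

    return [
        ParticleGT(
            id=i,
            center_x_px=float(xs[i]),
            center_y_px=float(ys[i]),
            diameter_um=float(diameters[i]),
            grey_level=int(greys[i]),
            pm_class=_MIXTURE_ORDER[cls_idx[i]],
        )
        for i in range(n)
    ]


def _disk_coverage(
    cx: float, cy: float, r_px: float, x0: int, y0: int, w: int, h: int, ss: int = 4
) -> np.ndarray:
    """Per-pixel area coverage of a disk over a patch, by ss×ss supersampling.

    Pixel (i, j) spans [i-0.5, i+0.5) × [j-0.5, j+0.5); coverage is the
    fraction of its ss² subsamples falling inside the circle.
    """
    sub_x = x0 - 0.5 + (np.arange(w * ss) + 0.5) / ss
    sub_y = y0 - 0.5 + (np.arange(h * ss) + 0.5) / ss
    dx2 = (sub_x - cx) ** 2
    dy2 = (sub_y - cy) ** 2
    inside = (dy2[:, None] + dx2[None, :]) <= r_px * r_px
    return inside.reshape(h, ss, w, ss).mean(axis=(1, 3))


def render_sensor_image(
    spec: SensorImageSpec,
    particles: Sequence[ParticleGT],
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render particles onto a textured near-white background.

    Returns an 8-bit RGB array of shape (height, width, 3) — the three
    channels are identical before any degradation — and the
    :class:`GroundTruth` echoing the inputs.  Each particle is an
    anti-aliased filled disk of diameter ``diameter_um × resolution`` px
    composited at its grey level; the rendered pixel area of an isolated
    disk matches π(d·r/2)² to sub-pixel accuracy.

    Bit-identical output for identical (spec, particles, seed).
    """
    h, w = spec.height_px, spec.width_px
    img = np.full((h, w), float(spec.background_mean), dtype=np.float32)
    if spec.background_sigma > 0:
        rng = np.random.default_rng(seed)
        img += spec.background_sigma * rng.standard_normal((h, w), dtype=np.float32)

    for p in particles:
        if not (0 <= p.center_x_px < w and 0 <= p.center_y_px < h):
            raise OutOfBoundsParticleError(
                f"particle {p.id} center ({p.center_x_px:.1f}, {p.center_y_px:.1f}) "
                f"outside {w}x{h} image"
            )
        r = p.diameter_um * spec.resolution_px_per_um / 2.0
        x0 = max(int(math.floor(p.center_x_px - r - 1)), 0)
        y0 = max(int(math.floor(p.center_y_px - r - 1)), 0)
        x1 = min(int(math.ceil(p.center_x_px + r + 1)) + 1, w)
        y1 = min(int(math.ceil(p.center_y_px + r + 1)) + 1, h)
        alpha = _disk_coverage(p.center_x_px, p.center_y_px, r, x0, y0, x1 - x0, y1 - y0)
        patch = img[y0:y1, x0:x1]
        patch *= 1.0 - alpha
        patch += np.float32(p.grey_level) * alpha

    grey8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(grey8[:, :, None], 3, axis=2)
    gt = GroundTruth(particles=tuple(particles), spec=spec, seed=seed)
    return rgb, gt


@dataclass(frozen=True)
class GridCell:
    """One cell of a generation grid: what to synthesize and how to degrade it."""

    spec: SensorImageSpec
    n: int
    mixture: tuple[float, float, float] = DEFAULT_MIXTURE
    degradation: "DegradationConfig | None" = None
    seed: int = 0
    min_gap_px: float = 1.0
    name: str = ""


def generate_dataset(grid: Sequence[GridCell], out_dir: str | Path) -> pd.DataFrame:
    """Materialize a grid of synthetic images plus ground truth on disk.

    Writes, per cell, ``<name>.png``, ``<name>.truth.json`` and a flat
    ``<name>.truth.csv``, and a ``manifest.csv`` linking them.  Idempotent:
    rerunning with the same grid rewrites identical bytes.
    """
    from .degrade import compose_degradations  # deferred: avoids import cycle
    from .io import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, cell in enumerate(grid):
        name = cell.name or f"cell_{i:04d}"
        try:
            particles = sample_particles(
                cell.spec, cell.n, cell.mixture, min_gap_px=cell.min_gap_px, seed=cell.seed
            )
            img, gt = render_sensor_image(cell.spec, particles, seed=cell.seed)
            if cell.degradation is not None:
                img = compose_degradations(img, cell.degradation)
            img_path = out / f"{name}.png"
            truth_json = out / f"{name}.truth.json"
            truth_csv = out / f"{name}.truth.csv"
            write_image(img, img_path)
            gt.to_json(truth_json)
            gt.to_dataframe().to_csv(truth_csv, index=False)
        except OSError as exc:
            raise OSError(f"I/O failure while writing grid cell {i} ({name}): {exc}") from exc
        noise = "" if cell.degradation is None else cell.degradation.describe()
        rows.append(
            {
                "image_path": img_path.name,
                "truth_path": truth_json.name,
                "n_particles": gt.n_total,
                "noise": noise,
                "seed": cell.seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["image_path", "truth_path", "n_particles", "noise", "seed"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
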
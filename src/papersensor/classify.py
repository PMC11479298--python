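"""Particle size classes and the dust-scale pollution rating.

Airborne particulate matter is conventionally binned by aerodynamic
equivalent diameter: PM1 (≤ 1 µm), PM2.5 (≤ 2.5 µm) and PM10 (≤ 10 µm),
with the smaller classes nested inside the larger ones.  For ground-truth
bookkeeping this module uses *disjoint* strata (a particle is labelled by
the tightest class it fits), while reporting code may count every particle
of diameter ≤ 10 µm toward the PM10 total.

The dust scale maps the areal density of captured particles (dots per cm²
on a jelly-coated paper sensor) onto four pollution levels.  The published
bands are stated on integers (<11, 11–25, 26–50, >50); real-valued
densities use the half-open convention [0,11) / [11,26) / [26,51) / [51,∞)
so that every integer lands exactly where the table puts it.
"""

from __future__ import annotations

import math
from enum import Enum

__all__ = [
    "PMClass",
    "DustLevel",
    "PM_DIAMETER_BOUNDS_UM",
    "DUST_SCALE_BANDS",
    "pm_class",
    "dust_scale_level",
    "dot_density",
]


class PMClass(str, Enum):
    """Disjoint particle-size strata by equivalent diameter (µm)."""

    PM1 = "PM1"
    PM2_5 = "PM2_5"
    PM10 = "PM10"
    OVERSIZE = "OVERSIZE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DustLevel(str, Enum):
    """Four-level pollution rating from dot density."""

    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"
    VERY_HIGH = "Very high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Upper diameter bound (inclusive, µm) of each finite class, in order.
PM_DIAMETER_BOUNDS_UM: tuple[tuple[float, PMClass], ...] = (
    (1.0, PMClass.PM1),
    (2.5, PMClass.PM2_5),
    (10.0, PMClass.PM10),
)

#: Half-open density bands [lo, hi) in dots per cm², lowest level first.
DUST_SCALE_BANDS: tuple[tuple[float, float, DustLevel], ...] = (
    (0.0, 11.0, DustLevel.LOW),
    (11.0, 26.0, DustLevel.MEDIUM),
    (26.0, 51.0, DustLevel.HIGH),
    (51.0, math.inf, DustLevel.VERY_HIGH),
)


def pm_class(diameter_um: float) -> PMClass:
    """Classify a particle by equivalent diameter.

    Upper bounds are inclusive ("10 µm or smaller" is PM10); anything above
    10 µm is OVERSIZE.  The four bands partition (0, ∞).

    Parameters
    ----------
    diameter_um : float
        Equivalent circular diameter in micrometres; must be positive.
    """
    d = float(diameter_um)
    if not math.isfinite(d) or d <= 0.0:
        raise ValueError(f"diameter_um must be a positive finite number, got {diameter_um!r}")
    for bound, cls in PM_DIAMETER_BOUNDS_UM:
        if d <= bound:
            return cls
    return PMClass.OVERSIZE


def dust_scale_level(dots_per_cm2: float) -> DustLevel:
    """Map a dot density to its pollution level.

    Bands: Low [0, 11), Medium [11, 26), High [26, 51), Very high [51, ∞),
    matching the integer table <11 / 11–25 / 26–50 / >50 exactly.
    """
    rho = float(dots_per_cm2)
    if not math.isfinite(rho) or rho < 0.0:
        raise ValueError(f"dots_per_cm2 must be non-negative and finite, got {dots_per_cm2!r}")
    for lo, hi, level in DUST_SCALE_BANDS:
        if lo <= rho < hi:
            return level
    raise AssertionError("unreachable: bands partition [0, inf)")  # pragma: no cover


def dot_density(n_total: int, area_cm2: float) -> float:
    """Areal particle density in dots per cm²."""
    if n_total < 0:
        raise ValueError(f"n_total must be non-negative, got {n_total}")
    a = float(area_cm2)
    if not math.isfinite(a) or a <= 0.0:
        raise ValueError(f"area_cm2 must be positive and finite, got {area_cm2!r}")
    return n_total / a
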
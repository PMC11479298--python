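"""Camera-degradation models: Gaussian noise, focus blur, white balance.

Three degradations emulate how a smartphone photograph of a paper sensor
differs from an ideal scan:

* **Gaussian noise** — additive iid N(mean, variance) per pixel and channel
  on the 0–255 digital-number (DN) scale, modelling sensor/electronic noise.
* **Focus blur** — a centered sharp rectangle covering ``focus_area`` % of
  each image dimension is preserved; outside it the image is Gaussian-blurred
  with σ = ``strength`` px, with a smooth transition band so no seam appears.
* **White balance** — a signed colour-temperature knob applying linear
  channel gains (red 1 + k·T, blue 1 − k·T, k = 0.01, green untouched);
  negative temperatures cool the image.

Each model is the identity at its null parameter, and
:func:`compose_degradations` applies them in capture order
(optics → camera processing → sensor noise).  All outputs are 8-bit,
clipped to [0, 255], and deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianNoiseParams",
    "FocusBlurParams",
    "WhiteBalanceParams",
    "DegradationConfig",
    "WB_GAIN_PER_UNIT",
    "add_gaussian_noise",
    "apply_focus_blur",
    "adjust_white_balance",
    "compose_degradations",
]

#: Channel-gain slope per white-balance temperature unit.
WB_GAIN_PER_UNIT = 0.01

#: Gaussian kernels are truncated at this many σ.
_TRUNCATE_SIGMA = 4.0


@dataclass(frozen=True)
class GaussianNoiseParams:
    mean: float = 0.0
    variance: float = 0.0  # DN²

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be non-negative, got {self.variance}")


@dataclass(frozen=True)
class FocusBlurParams:
    focus_area: float = 100.0  # percent of each dimension kept sharp, (0, 100]
    strength: float = 0.0  # blur σ in px outside the sharp region

    def __post_init__(self) -> None:
        if not 0 < self.focus_area <= 100:
            raise ValueError(f"focus_area must be in (0, 100], got {self.focus_area}")
        if self.strength < 0:
            raise ValueError(f"strength must be non-negative, got {self.strength}")


@dataclass(frozen=True)
class WhiteBalanceParams:
    temperature: float = 0.0  # signed; the sweeps use -1 .. -20


@dataclass(frozen=True)
class DegradationConfig:
    """Composition of the three models; absent components are identities.

    Application order is fixed to the physical capture chain:
    focus blur (optics) → white balance (camera processing) →
    Gaussian noise (sensor electronics).
    """

    gaussian: Optional[GaussianNoiseParams] = None
    focus_blur: Optional[FocusBlurParams] = None
    white_balance: Optional[WhiteBalanceParams] = None
    seed: int = 0

    ORDER = ("focus_blur", "white_balance", "gaussian")

    def with_seed(self, seed: int) -> "DegradationConfig":
        return replace(self, seed=seed)

    def describe(self) -> str:
        parts = []
        if self.focus_blur is not None:
            parts.append(f"blur(area={self.focus_blur.focus_area:g},s={self.focus_blur.strength:g})")
        if self.white_balance is not None:
            parts.append(f"wb(T={self.white_balance.temperature:g})")
        if self.gaussian is not None:
            parts.append(f"gauss(mean={self.gaussian.mean:g},var={self.gaussian.variance:g})")
        return "+".join(parts) if parts else "clean"


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim not in (2, 3) or img.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit 2-D or 3-D image array, got {img.dtype} ndim={img.ndim}")
    return img


def _to_uint8(img_f: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img_f), 0, 255).astype(np.uint8)


def add_gaussian_noise(
    image: np.ndarray, mean: float, variance: float, seed: int = 0
) -> np.ndarray:
    """Add per-pixel iid Gaussian noise on the DN scale, clip and requantize.

    ``variance`` is in DN² (so σ = √variance).  Noise is drawn independently
    for every pixel and channel; deterministic per seed.
    """
    img = _check_image(image)
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    if mean == 0 and variance == 0:
        return img.copy()
    out = img.astype(np.float32)
    out += np.float32(mean)
    if variance > 0:
        rng = np.random.default_rng(seed)
        out += np.float32(np.sqrt(variance)) * rng.standard_normal(img.shape, dtype=np.float32)
    return _to_uint8(out)


def _axis_weight(n: int, focus_area: float, band: float) -> np.ndarray:
    """Sharpness weight along one axis: 1 inside the focus half-width, raised-
    cosine ramp to 0 across ``band`` pixels outside it."""
    half = (focus_area / 100.0) * n / 2.0
    dist = np.abs(np.arange(n, dtype=np.float64) - (n - 1) / 2.0)
    t = np.clip((dist - half) / band, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def apply_focus_blur(image: np.ndarray, focus_area: float, strength: float) -> np.ndarray:
    """Blur the periphery while keeping a centered region sharp.

    ``focus_area`` is the percentage of each image dimension spanned by the
    sharp rectangle; outside it a Gaussian blur of σ = ``strength`` px is
    applied, blended over a transition band 3σ wide.  ``focus_area == 100``
    or ``strength == 0`` is the identity.
    """
    img = _check_image(image)
    if not 0 < focus_area <= 100:
        raise ValueError(f"focus_area must be in (0, 100], got {focus_area}")
    if strength < 0:
        raise ValueError(f"strength must be non-negative, got {strength}")
    if focus_area == 100 or strength == 0:
        return img.copy()

    sigma = (strength, strength) if img.ndim == 2 else (strength, strength, 0)
    blurred = ndimage.gaussian_filter(
        img.astype(np.float32), sigma=sigma, mode="reflect", truncate=_TRUNCATE_SIGMA
    )
    band = max(3.0 * strength, 1.0)
    wy = _axis_weight(img.shape[0], focus_area, band)
    wx = _axis_weight(img.shape[1], focus_area, band)
    w = (wy[:, None] * wx[None, :]).astype(np.float32)
    if img.ndim == 3:
        w = w[:, :, None]
    out = w * img.astype(np.float32) + (1.0 - w) * blurred
    return _to_uint8(out)


def adjust_white_balance(image: np.ndarray, temperature: float) -> np.ndarray:
    """Shift the red/blue channel balance by a signed temperature.

    Linear gains: red × (1 + 0.01·T), blue × (1 − 0.01·T), clamped at 0;
    the green channel is returned bit-identical.  Negative temperatures
    therefore cool the image (red down, blue up).  T = 0 is the identity.
    """
    img = _check_image(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("white balance requires a 3-channel RGB image")
    if temperature == 0:
        return img.copy()
    gain_r = max(1.0 + WB_GAIN_PER_UNIT * temperature, 0.0)
    gain_b = max(1.0 - WB_GAIN_PER_UNIT * temperature, 0.0)
    out = np.empty_like(img)
    out[:, :, 0] = _to_uint8(img[:, :, 0].astype(np.float32) * np.float32(gain_r))
    out[:, :, 1] = img[:, :, 1]
    out[:, :, 2] = _to_uint8(img[:, :, 2].astype(np.float32) * np.float32(gain_b))
    return out


def compose_degradations(image: np.ndarray, config: DegradationConfig) -> np.ndarray:
    """Apply the configured degradations in capture order.

    Order: focus blur → white balance → Gaussian noise; absent components
    are skipped.  Deterministic for a fixed ``config.seed``.
    """
    img = _check_image(image)
    out = img
    if config.focus_blur is not None:
        out = apply_focus_blur(out, config.focus_blur.focus_area, config.focus_blur.strength)
    if config.white_balance is not None:
        out = adjust_white_balance(out, config.white_balance.temperature)
    if config.gaussian is not None:
        out = add_gaussian_noise(
            out, config.gaussian.mean, config.gaussian.variance, seed=config.seed
        )
    return out.copy() if out is img else out
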
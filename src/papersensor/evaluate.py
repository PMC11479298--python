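"""Count-accuracy metric and the noise-robustness sweep experiments.

Detection quality is measured by a single count-based metric,

    accuracy = 100 × (number of detected particles) / (actual number),

with no spatial matching of detections to ground truth: a merged pair costs
one count, a false positive adds one, and values above 100 are reported
as-is with an over-detection flag.

:func:`run_sweep` reproduces the five noise-robustness experiment families:
Gaussian noise alone, focus blur alone, white-balance adjustment alone,
Gaussian + white balance, and all three combined.  For every
(particle count × noise condition × seed) cell it synthesizes a clean
sensor image, degrades it, runs the detector, and records the accuracy.
Clean images are generated once per (count, seed) and shared across noise
conditions.  Experiments default to a PM10-only particle mixture, matching
images tagged with a pre-known quantity of PM10 particles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .degrade import (
    DegradationConfig,
    FocusBlurParams,
    GaussianNoiseParams,
    WhiteBalanceParams,
    compose_degradations,
)
from .detect import CalibrationInfo, DetectionParams, detect
from .synthgen import PM10_ONLY_MIXTURE, SensorImageSpec, render_sensor_image, sample_particles

__all__ = [
    "NoiseCondition",
    "SweepConfig",
    "AccuracyReport",
    "accuracy",
    "paper_noise_grid",
    "run_sweep",
    "report",
    "DEFAULT_PARTICLE_COUNTS",
]

logger = logging.getLogger(__name__)

#: Particle counts swept in the robustness experiments.
DEFAULT_PARTICLE_COUNTS: tuple[int, ...] = (100, 200, 300, 400, 500, 600, 700, 800)

_ROW_COLUMNS = [
    "condition",
    "family",
    "noise",
    "n_particles",
    "seed",
    "detected",
    "actual",
    "accuracy_pct",
    "over_detected",
    "error",
]


def accuracy(detected: int, actual: int) -> float:
    """Count accuracy in percent: 100 × detected / actual.

    Over-detection (detected > actual) yields values above 100, returned
    as-is; callers flag them.  ``actual`` must be positive.
    """
    if actual <= 0:
        raise ValueError(f"actual must be positive, got {actual}")
    if detected < 0:
        raise ValueError(f"detected must be non-negative, got {detected}")
    return 100.0 * detected / actual


@dataclass(frozen=True)
class NoiseCondition:
    """One cell of the noise grid: a named degradation configuration."""

    family: str
    label: str
    config: DegradationConfig


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for a robustness sweep."""

    particle_counts: tuple[int, ...] = DEFAULT_PARTICLE_COUNTS
    noise_grid: tuple[NoiseCondition, ...] = ()
    n_seeds: int = 10
    spec: SensorImageSpec = field(default_factory=SensorImageSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    mixture: tuple[float, float, float] = PM10_ONLY_MIXTURE
    min_gap_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if any(c <= 0 for c in self.particle_counts):
            raise ValueError("particle_counts must be positive")


def paper_noise_grid() -> tuple[NoiseCondition, ...]:
    """The five experiment families at their published parameter endpoints.

    Gaussian mean 1–5 / variance 4–8; focus area 100–70 / blur strength 1–4;
    white-balance temperature −1 to −20; plus the two stated combinations.
    Each family contributes its mild and severe endpoint.
    """
    g_lo = GaussianNoiseParams(mean=1.0, variance=4.0)
    g_hi = GaussianNoiseParams(mean=5.0, variance=8.0)
    b_lo = FocusBlurParams(focus_area=100.0, strength=1.0)
    b_hi = FocusBlurParams(focus_area=70.0, strength=4.0)
    wb_lo = WhiteBalanceParams(temperature=-1.0)
    wb_hi = WhiteBalanceParams(temperature=-20.0)
    return (
        NoiseCondition("gaussian", "mean1_var4", DegradationConfig(gaussian=g_lo)),
        NoiseCondition("gaussian", "mean5_var8", DegradationConfig(gaussian=g_hi)),
        NoiseCondition("blur", "area100_s1", DegradationConfig(focus_blur=b_lo)),
        NoiseCondition("blur", "area70_s4", DegradationConfig(focus_blur=b_hi)),
        NoiseCondition("white_balance", "temp-1", DegradationConfig(white_balance=wb_lo)),
        NoiseCondition("white_balance", "temp-20", DegradationConfig(white_balance=wb_hi)),
        NoiseCondition(
            "gaussian_wb", "mean1_var4_temp-1",
            DegradationConfig(gaussian=g_lo, white_balance=wb_lo),
        ),
        NoiseCondition(
            "gaussian_wb", "mean5_var8_temp-20",
            DegradationConfig(gaussian=g_hi, white_balance=wb_hi),
        ),
        NoiseCondition(
            "gaussian_blur_wb", "mild",
            DegradationConfig(gaussian=g_lo, focus_blur=b_lo, white_balance=wb_lo),
        ),
        NoiseCondition(
            "gaussian_blur_wb", "severe",
            DegradationConfig(gaussian=g_hi, focus_blur=b_hi, white_balance=wb_hi),
        ),
    )


def _derive_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class AccuracyReport:
    """Tidy per-row accuracies of a sweep plus aggregation helpers."""

    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean/sd accuracy per (family, condition, particle count)."""
        ok = self.rows[self.rows["error"].isna()]
        agg = (
            ok.groupby(["family", "condition", "n_particles"], sort=True)["accuracy_pct"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_accuracy_pct", "std": "sd_accuracy_pct", "count": "n_runs"})
        )
        return agg

    def family_means(self) -> pd.Series:
        ok = self.rows[self.rows["error"].isna()]
        return ok.groupby("family")["accuracy_pct"].mean()

    def grand_mean_accuracy(self) -> float:
        """Mean accuracy over every successful row of the sweep."""
        ok = self.rows[self.rows["error"].isna()]
        if ok.empty:
            raise ValueError("report contains no successful rows")
        return float(ok["accuracy_pct"].mean())


def run_sweep(config: SweepConfig, base_seed: int = 0) -> AccuracyReport:
    """Execute a sweep grid and collect per-run count accuracies.

    For each (count, seed) a clean image is generated once (particle
    placement and rendering seeded deterministically from ``base_seed``)
    and every noise condition in the grid — an empty grid means clean
    images — is applied to it and detected.  A failing condition is
    recorded in its row's ``error`` column rather than dropped.
    """
    conditions: Sequence[NoiseCondition] = config.noise_grid or (
        NoiseCondition("clean", "clean", DegradationConfig()),
    )
    calibration = CalibrationInfo(px_per_cm=config.spec.px_per_cm)
    records: list[dict] = []
    for count in config.particle_counts:
        for s in range(config.n_seeds):
            gen_seed = _derive_seed(base_seed, count, s)
            particles = sample_particles(
                config.spec, count, config.mixture, min_gap_px=config.min_gap_px, seed=gen_seed
            )
            clean, gt = render_sensor_image(config.spec, particles, seed=gen_seed)
            for ci, cond in enumerate(conditions):
                row = {
                    "condition": cond.label,
                    "family": cond.family,
                    "noise": cond.config.describe(),
                    "n_particles": count,
                    "seed": s,
                    "detected": np.nan,
                    "actual": gt.n_total,
                    "accuracy_pct": np.nan,
                    "over_detected": False,
                    "error": None,
                }
                try:
                    cfg = cond.config.with_seed(_derive_seed(base_seed, count, s, ci))
                    noisy = compose_degradations(clean, cfg)
                    result = detect(noisy, config.detection, calibration)
                    row["detected"] = result.n_total
                    row["accuracy_pct"] = accuracy(result.n_total, gt.n_total)
                    row["over_detected"] = result.n_total > gt.n_total
                except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                    logger.warning(
                        "sweep condition failed: family=%s label=%s n=%d seed=%d: %s",
                        cond.family, cond.label, count, s, exc,
                    )
                    row["error"] = f"{type(exc).__name__}: {exc}"
                records.append(row)
    return AccuracyReport(rows=pd.DataFrame(records, columns=_ROW_COLUMNS))


def report(rep: AccuracyReport, out_dir: str | Path) -> list[Path]:
    """Write the tidy rows, aggregates, and one accuracy-vs-count plot per family.

    Returns the list of files written; raises on an empty report.
    """
    if rep.rows.empty:
        raise ValueError("cannot report an empty sweep")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows_path = out / "accuracy_rows.csv"
    rep.rows.to_csv(rows_path, index=False)
    written.append(rows_path)
    agg = rep.aggregate()
    agg_path = out / "accuracy_summary.csv"
    agg.to_csv(agg_path, index=False)
    written.append(agg_path)

    for family, sub in agg.groupby("family"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for condition, cs in sub.groupby("condition"):
            cs = cs.sort_values("n_particles")
            ax.errorbar(
                cs["n_particles"], cs["mean_accuracy_pct"], yerr=cs["sd_accuracy_pct"],
                marker="o", capsize=3, label=str(condition),
            )
        ax.set_xlabel("particles per image")
        ax.set_ylabel("count accuracy (%)")
        ax.set_title(f"{family}")
        ax.legend(fontsize=8)
        ax.grid(True, alpha=0.3)
        fig.tight_layout()
        path = out / f"accuracy_{family}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
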
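import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import papersensor as ps

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_spec() -> ps.SensorImageSpec:
    """A small, fast sensor-image spec at the working resolution of 1 px/µm."""
    return ps.SensorImageSpec(width_px=400, height_px=400)


@pytest.fixture
def calibration() -> ps.CalibrationInfo:
    """Calibration matching 1 px/µm (10,000 px per cm)."""
    return ps.CalibrationInfo(px_per_cm=1e4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
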
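from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import lapmotion as lm

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def kinovea_fixture_path() -> Path:
    return DATA_DIR / "kinovea_track.xml"


@pytest.fixture
def calibration() -> lm.Calibration:
    return lm.Calibration(pixels_per_cm=50.0, frame_rate_hz=25.0)


def make_random_trajectory(seed: int, n: int = 100, scale: float = 1.0) -> lm.Trajectory:
    """A generic seeded random walk in cm (not the synthetic skill model)."""
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0.0, scale, size=(n, 2)), axis=0)
    return lm.Trajectory(frames=np.arange(n), xy_cm=xy, frame_rate_hz=30.0, label=f"rw{seed}")


@pytest.fixture
def random_trajectory() -> lm.Trajectory:
    return make_random_trajectory(seed=42)


@pytest.fixture
def reference_thresholds() -> lm.ReferenceThresholds:
    """Hand-set thresholds with expert medians on the small side, as in practice."""
    return lm.ReferenceThresholds(
        medians={
            "L": {"expert_median": 80.0, "novice_median": 220.0},
            "A": {"expert_median": 0.26, "novice_median": 0.75},
            "J": {"expert_median": 1.0, "novice_median": 40.0},
        }
    )
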
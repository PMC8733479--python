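import numpy as np
import pytest

from bradykinet.simulate import CohortSpec, MotionSimParams, simulate_cohort
from bradykinet.types import HandLandmarkFrame, N_KEYPOINTS


def make_frame(frame_index: int, xy: np.ndarray, confidence: float = 1.0) -> HandLandmarkFrame:
    """Build a HandLandmarkFrame from (21, 2) coordinates."""
    kp = np.column_stack([xy, np.full(len(xy), confidence)])
    return HandLandmarkFrame(frame_index, kp)


def constant_frames(n: int, xy: np.ndarray) -> list:
    return [make_frame(i, xy) for i in range(n)]


def base_xy(rng=None) -> np.ndarray:
    """An arbitrary non-degenerate 21-point layout."""
    rng = rng or np.random.default_rng(0)
    return rng.uniform(50, 300, size=(N_KEYPOINTS, 2))


@pytest.fixture(scope="session")
def noise_free_params() -> MotionSimParams:
    return MotionSimParams(
        cadence_hz=2.0,
        base_amplitude=0.8,
        decrement_rate=0.0,
        hesitation_prob=0.0,
        jitter_px_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but classifiable cohort, shared across evaluation tests."""
    spec = CohortSpec(
        n_pd=8, n_hs=8, seed=11, tasks=("finger_tapping",), conditions=("unilateral",)
    )
    return simulate_cohort(spec)
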
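import warnings

import numpy as np
import pytest

from vidgait.pose_io import PoseSequence
from vidgait.synthetic_gait import WalkSpec, make_cohort, simulate_walk


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_sequence():
    """60 frames, 4 joints, smooth deterministic 2D trajectories."""
    t = np.arange(60) / 30.0
    coords = np.empty((60, 4, 2))
    coords[:, 0] = np.column_stack([300 + 5 * t, 240 + 2 * t])  # left_hip
    coords[:, 1] = np.column_stack([320 + 5 * t, 240 + 2 * t])  # right_hip
    coords[:, 2] = np.column_stack([290 + 30 * t, 400 + np.sin(t)])  # left_ankle
    coords[:, 3] = np.column_stack([330 + 30 * t, 400 + np.cos(t)])  # right_ankle
    scheme = {"left_hip": 0, "right_hip": 1, "left_ankle": 2, "right_ankle": 3}
    conf = np.full((60, 4), 0.9)
    return PoseSequence(coords=coords, fps=30.0, joint_scheme=scheme, confidence=conf)


@pytest.fixture(scope="session")
def clean_walk():
    """One deterministic noise-free simulated bout (away from the camera)."""
    spec = WalkSpec(seed=11, direction="away")
    return simulate_walk(spec)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(8, preset="normal", seed=31)
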
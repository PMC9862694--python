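import numpy as np
import pytest

from bandrep.datamodel_io import IMUTrack, JointTrack
from bandrep.synthetic import BASE_POSE, TEMPLATES, SimulationConfig, simulate_session


@pytest.fixture
def identity_imu_rows():
    """Identity-quaternion, at-rest rows (1 g on the vertical channel)."""
    return ["0.0,0.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,1.0"] * 5


@pytest.fixture
def small_imu_track(rng):
    q = rng.normal(size=(20, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    gyro = rng.normal(0, 50, size=(20, 3))
    acc = rng.normal(0, 0.5, size=(20, 3))
    return IMUTrack(np.column_stack([q, gyro, acc]), fps=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def static_track():
    """300-frame motionless skeleton in pixel space, full confidence."""
    n = 300
    x = np.tile(BASE_POSE[:, 0], (n, 1))
    y = np.tile(BASE_POSE[:, 1], (n, 1))
    conf = np.full((n, 25), 0.9)
    return JointTrack(x=x, y=y, conf=conf, fps=30.0)


@pytest.fixture
def clean_session():
    """Noise-free 10-repetition seated-row recording."""
    rec, truth = simulate_session(TEMPLATES["Ex3"],
                                  SimulationConfig(reps=10, seed=42))
    return rec, truth
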
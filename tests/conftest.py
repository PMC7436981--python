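import numpy as np
import pytest

from copstab import CalibrationProfile, CoPTrajectory, HomePosition, RFASet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_calib():
    """Symmetric calibration: 40 mm max excursion, 30 mm target distance."""
    return CalibrationProfile(
        {"forward": 40.0, "backward": 40.0, "left": 40.0, "right": 40.0}
    )


@pytest.fixture
def square_rfas(square_calib):
    """RFAs centred at the origin with 30 mm reference distance each side."""
    return RFASet(center=(0.0, 0.0), reference=square_calib.target_distance)


@pytest.fixture
def origin_home():
    return HomePosition(0.0, 0.0)


def make_traj(x, y, fs=100.0):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / fs
    return CoPTrajectory(t=t, x=x, y=np.asarray(y, dtype=float), fs=fs)


@pytest.fixture
def random_traj(rng):
    """A 12-s random-walk-ish trajectory at 100 Hz."""
    n = 1200
    x = np.cumsum(rng.normal(0, 0.5, n))
    y = np.cumsum(rng.normal(0, 0.5, n))
    return make_traj(x, y)
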
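import numpy as np
import pytest

from swimtrap import Trajectory, Trap

FS = 500.0
DT = 1.0 / FS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_circle(radius=10.0, omega=2.0, dt=1e-3, duration=6.0, ccw=True,
                trap=None, centre=(0.0, 0.0)):
    """Uniform circular motion, CCW for positive omega."""
    t = np.arange(0.0, duration, dt)
    sgn = 1.0 if ccw else -1.0
    x = centre[0] + radius * np.cos(sgn * omega * t)
    y = centre[1] + radius * np.sin(sgn * omega * t)
    return Trajectory(t, x, y, frame_interval=dt, trap=trap)


def make_straight(v=(3.0, 4.0), dt=DT, duration=2.0, trap=None):
    t = np.arange(0.0, duration, dt)
    return Trajectory(t, v[0] * t, v[1] * t, frame_interval=dt, trap=trap)


@pytest.fixture
def circle_track():
    return make_circle()


@pytest.fixture
def straight_track():
    return make_straight()


@pytest.fixture
def disk_trap():
    return Trap(0.0, 0.0, 60.0)
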
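import numpy as np
import pytest

from kinesym.core import Recording, default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(layout, duration_s=10.0, rate=32.0, fill=0.0):
    """A constant-fill recording covering all 17 sensors."""
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    gyro = {s: np.full((n, 3), float(fill)) for s in layout.placements}
    accel = {s: np.full((n, 3), float(fill)) for s in layout.placements}
    return Recording(sampling_rate=rate, timestamps=t, gyro=gyro, accel=accel)


@pytest.fixture
def zero_recording(layout):
    return make_recording(layout)
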
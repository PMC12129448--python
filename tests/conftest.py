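import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cochleartune.session import SweepSpec

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def short_probe():
    """Reduced-span probe sweep for fast unit tests (same 50 kHz rate)."""
    return SweepSpec(1000.0, 4000.0, 0.3, 40.0, ramp=0.01)


@pytest.fixture(scope="session")
def short_suppressor():
    return SweepSpec(1040.0, 4040.0, 0.3, 55.0, ramp=0.01)


@pytest.fixture(scope="session")
def octave_grid():
    """96 points/octave grid factory around a center frequency."""

    def make(cf, octaves=3.0, per_octave=96, offset=0.37):
        j = np.arange(-octaves * per_octave, octaves * per_octave + 1)
        return cf * 2.0 ** ((j - offset) / per_octave)

    return make
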
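import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imspeak import Measurement, Peak, PeakList

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_measurement(intensity, sample_id="s0", rt0=0.0, drt=1.0, ik0_0=0.4, dik0=0.0015):
    """Wrap a raw array in a Measurement with evenly spaced axes."""
    intensity = np.asarray(intensity, dtype=float)
    n_rt, n_ik0 = intensity.shape
    return Measurement(
        sample_id=sample_id,
        rt_axis=rt0 + drt * np.arange(n_rt),
        ik0_axis=ik0_0 + dik0 * np.arange(n_ik0),
        intensity=intensity,
    )


def make_peaklist(mid, positions, intensity=10.0):
    """PeakList from (rt, ik0) tuples with a common intensity."""
    return PeakList(
        measurement_id=mid,
        peaks=[Peak(measurement_id=mid, rt=rt, ik0=ik0, intensity=intensity)
               for rt, ik0 in positions],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
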
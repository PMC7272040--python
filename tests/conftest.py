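import numpy as np
import pytest

from reefscape.profiles import ElevationProfile


def make_profile(z_fn, length=5.0, resolution=0.005, x0=0.0):
    """Profile from a callable z(x) sampled on a uniform grid."""
    x = np.arange(0.0, length + resolution / 2, resolution)
    x = x[x <= length + 1e-12]
    z = np.asarray([z_fn(v) for v in x], dtype=float)
    return ElevationProfile(x=x0 + x, z=z)


@pytest.fixture
def flat_profile():
    return make_profile(lambda x: 0.0)


@pytest.fixture
def ramp_profile():
    """Uniform 45-degree ramp over 5 m."""
    return make_profile(lambda x: x)


@pytest.fixture
def sawtooth_profile():
    """45-degree sawtooth with 0.25 m teeth over 5 m."""

    def tooth(x):
        p = x % 0.5
        return p if p <= 0.25 else 0.5 - p

    return make_profile(tooth)
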
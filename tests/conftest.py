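import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rstrack import Track

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_planar_track(rng, n, dt_s=300.0, spread=2.0, jitter_t=False):
    """A random planar track: Gaussian steps, roughly regular cadence."""
    dts = rng.uniform(0.3 * dt_s, 1.7 * dt_s, n - 1) if jitter_t else np.full(n - 1, dt_s)
    times = np.concatenate([[0.0], np.cumsum(dts)])
    x = np.cumsum(rng.normal(0, spread, n))
    y = np.cumsum(rng.normal(0, spread, n))
    return Track(times, x, y, animal_id="rand", crs_mode="planar")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def collinear_track():
    """Fixes at x = 0..4 km on a line, one every 5 minutes."""
    return Track(np.arange(5) * 300.0, np.arange(5.0), np.zeros(5), crs_mode="planar")


@pytest.fixture
def random_track(rng):
    return make_planar_track(rng, 40)
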
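import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinerecon import PhantomSpec, build_pairs, make_spine_phantom

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny phantom for fast unit tests."""
    return PhantomSpec(volume_shape=(32, 32, 48), n_vertebrae=2,
                       body_radius_range=(4.0, 5.0),
                       body_height_range=(6.0, 8.0),
                       process_length_range=(3.0, 5.0),
                       gap=2, noise_sd=10.0, start_code="T11", seed=7)


@pytest.fixture(scope="session")
def small_record(small_spec):
    return make_spine_phantom(small_spec)


@pytest.fixture(scope="session")
def small_pairs(small_record):
    return build_pairs(small_record, size=16, radius=2)
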
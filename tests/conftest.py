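import numpy as np
import pytest

from svdnet.config import SimulationConfig
from svdnet.phantom import make_bundle_phantom
from svdnet.simulate import simulate_cohort


@pytest.fixture(scope="session")
def straight_phantom():
    return make_bundle_phantom(shape=(20, 10, 10))


@pytest.fixture(scope="session")
def bent_phantom():
    return make_bundle_phantom(shape=(20, 20, 10), bend_angle=90.0)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort config for fast end-to-end tests."""
    return SimulationConfig(n_subjects=40, n_retained=(40, 39, 28), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, keep_connectomes=True)


@pytest.fixture(scope="session")
def oracle_rng():
    return np.random.default_rng(20260926)
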
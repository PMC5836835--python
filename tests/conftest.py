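import numpy as np
import pytest

from terius import ReferenceProfile
from terius.pipeline import train_from_fixture
from terius.simulate import SimulationConfig, simulate_fixture


@pytest.fixture
def biased_profile():
    """Reference profile with a typical first-position ribosome bias."""
    return ReferenceProfile(np.array([0.6, 0.2, 0.2]), np.array([1 / 3] * 3))


@pytest.fixture(scope="session")
def default_fixture():
    """One seeded synthetic benchmark at the generator's default conditions."""
    return simulate_fixture(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def trained_default(default_fixture):
    """Both classifiers trained on the default synthetic benchmark."""
    return train_from_fixture(default_fixture, rng_seed=11)
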
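import numpy as np
import pytest

from mfneuron import PopulationLayout, sample_initial_conditions
from mfneuron.presets import (
    default_init_laws,
    fhn_one_population,
    fhn_two_population,
    hh_one_population,
)


@pytest.fixture(scope="session")
def fhn_spec():
    return fhn_one_population()


@pytest.fixture(scope="session")
def fhn_zero_spec():
    """One FHN population with every interaction parameter zero."""
    return fhn_one_population(J_bar=0.0, sigma_J=0.0)


@pytest.fixture(scope="session")
def fhn2_spec():
    return fhn_two_population()


@pytest.fixture(scope="session")
def hh_spec():
    return hh_one_population()


@pytest.fixture(scope="session")
def fhn_laws(fhn_spec):
    return default_init_laws(fhn_spec)


@pytest.fixture
def small_network(fhn_spec, fhn_laws):
    layout = PopulationLayout.from_proportions(fhn_spec, 10)
    init = sample_initial_conditions(fhn_spec, fhn_laws, layout, seed=42)
    return layout, init


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
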
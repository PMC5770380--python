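import numpy as np
import pytest

from chromofret import kinetics as kin


@pytest.fixture(scope="session")
def pair568():
    return kin.ALEXA568_647


@pytest.fixture(scope="session")
def pair488():
    return kin.ALEXA488_647


@pytest.fixture(scope="session")
def species_pair(pair568):
    hi = kin.FRETSpecies("compact", pair568, efficiency=0.8)
    lo = kin.FRETSpecies("open", pair568, efficiency=0.05)
    return hi, lo


@pytest.fixture
def two_state(species_pair):
    hi, lo = species_pair
    return kin.two_state_model(hi, lo, relaxation_time=1e-3, population0=0.4)


def make_single_species_model(pair, efficiency):
    sp = kin.FRETSpecies("single", pair, efficiency=efficiency)
    return kin.KineticModel([sp], np.zeros((1, 1)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
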
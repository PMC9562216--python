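import numpy as np
import pytest

from gaitevents import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def hs_trial():
    return simulate_trial(SimConfig(pattern="HS", n_strides=5, seed=101))


@pytest.fixture(scope="session")
def mf_trial():
    return simulate_trial(SimConfig(pattern="MF", n_strides=5, seed=102))


@pytest.fixture(scope="session")
def ff_trial():
    return simulate_trial(SimConfig(pattern="FF", n_strides=5, seed=103))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
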
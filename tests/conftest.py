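import numpy as np
import pytest

from endonet import DynamicsParams, make_random_network, make_repressilator, make_toggle_switch
from endonet.synthetic import repressilator_params


@pytest.fixture(scope="session")
def toggle():
    return make_toggle_switch()


@pytest.fixture(scope="session")
def repressilator():
    return make_repressilator()


@pytest.fixture(scope="session")
def fixed_eta_params():
    """Classical fixed-degradation mode (eta = 1), used for oracle checks."""
    return DynamicsParams(eta_dynamics=False, eta_fixed=1.0)


@pytest.fixture(scope="session")
def osc_params():
    return repressilator_params()


@pytest.fixture(scope="session")
def gc_scale_network():
    """Random fixture at the scale of the curated gastric network."""
    return make_random_network(55, 253, seed=7)


@pytest.fixture(scope="session")
def toggle_ensemble(toggle, fixed_eta_params):
    from endonet import find_attractors

    return find_attractors(toggle, fixed_eta_params, n_samples=80, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
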
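import numpy as np
import pytest

from lesionnet import Connectome, make_atlas, make_hub_recovery_network


@pytest.fixture(scope="session")
def atlas78():
    return make_atlas()


@pytest.fixture(scope="session")
def hub_network(atlas78):
    return make_hub_recovery_network(atlas78, n_hubs=8, seed=1)


@pytest.fixture(scope="session")
def hub_connectome(atlas78, hub_network):
    return Connectome(weights=np.abs(hub_network.partial_corr), atlas=atlas78)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
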
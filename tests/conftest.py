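import numpy as np
import pytest

from dfba_pdo import KineticParams, ObjectiveSpec, build_reduced_network


@pytest.fixture(scope="session")
def network():
    return build_reduced_network()


@pytest.fixture(scope="session")
def kinetics():
    return KineticParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def excess_objective(network):
    return ObjectiveSpec(0.04, network.atp_production_flux_ids)


@pytest.fixture(scope="session")
def limitation_objective(network):
    return ObjectiveSpec(1.0, network.atp_production_flux_ids)
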
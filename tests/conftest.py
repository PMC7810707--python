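import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import contextflux as cf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy3():
    return cf.toy3()


@pytest.fixture(scope="session")
def toy_bypass():
    return cf.toy_bypass()


@pytest.fixture(scope="session")
def toy3_fed(toy3):
    """TOY3 with the uptake exchange opened to 10 flux units."""
    return cf.apply_rich_media(toy3, 10.0)


@pytest.fixture(scope="session")
def toy3_samples(toy3_fed):
    """5000 ACHR points on the fed TOY3 chain (1-D polytope, biomass in [0, 10])."""
    return cf.achr_sample(toy3_fed, cf.SamplerConfig(points=5000, seed=11))


@pytest.fixture(scope="session")
def two_chain_network():
    """Two independent chains: a 2-D axis-aligned box in the chain fluxes."""
    spec = cf.ToyNetworkSpec(
        chain_lengths=(3, 3), uptake_bound=10.0, internal_bound=7.0, seed=0
    )
    return cf.make_toy_network(spec)


def assert_steady_state(network, matrix, tol=1e-6):
    S = cf.stoichiometric_matrix(network)
    V = matrix.values[network.reaction_ids].to_numpy()
    residual = np.abs(S @ V.T).max()
    assert residual < tol, f"steady-state residual {residual:.3g} exceeds {tol}"
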
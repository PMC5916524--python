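import numpy as np
import pytest

from spportrait import FieldModel
from spportrait.models import RM_LIMIT_CYCLE_OVERRIDES, fixture_network
from spportrait.reaction_network import parse_network

RM_DOMAIN = [(0.0, 12.0), (0.0, 3.0)]


@pytest.fixture(scope="session")
def ant_net():
    # r=10, eps=0.01, N=1000 -> N_C/N = 1 exactly; tests override as needed
    return fixture_network("foraging_colony")


@pytest.fixture(scope="session")
def ant_model(ant_net):
    return FieldModel.from_network(ant_net)


@pytest.fixture(scope="session")
def rm_net():
    return fixture_network("rosenzweig_macarthur")


@pytest.fixture(scope="session")
def rm_model(rm_net):
    return FieldModel.from_network(rm_net)  # N = 80


@pytest.fixture(scope="session")
def rm_builder(rm_net):
    def build(N, **params):
        return FieldModel.from_network(rm_net, params=params or None, N=N)

    return build


@pytest.fixture(scope="session")
def rm_lc_net():
    return fixture_network("rosenzweig_macarthur", RM_LIMIT_CYCLE_OVERRIDES)


@pytest.fixture(scope="session")
def immigration_death_net():
    return parse_network(
        """
species: [X]
parameters: {q: 1.0, c: 1.0}
reactions:
  - "0 -> X @ q"
  - "X -> 0 @ c"
system_size: 100
"""
    )


@pytest.fixture(scope="session")
def rm_domain():
    return RM_DOMAIN


def grid_points(domain, n=7):
    axes = [np.linspace(lo, hi, n) for lo, hi in domain]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)
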
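import numpy as np
import pytest

import hepatokin as hk
from hepatokin.simulate import ClampSet


@pytest.fixture(scope="session")
def network():
    return hk.build_network()


@pytest.fixture(scope="session")
def fasted_reference(network):
    """Canonical fasted state: 4 mM glucose, low glycogen store."""
    return hk.steady_state(network,
                           ClampSet(glucose=4.0, glycogen_fill=0.15),
                           "fasted")


@pytest.fixture(scope="session")
def fed_reference(network):
    """Canonical fed state: 10 mM glucose, high glycogen store."""
    return hk.steady_state(network,
                           ClampSet(glucose=10.0, glycogen_fill=0.8),
                           "fed")


@pytest.fixture(scope="session")
def normal_reference(network):
    """Normal-state set point reference (free for regulation freezing)."""
    return hk.reference_state(network)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
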
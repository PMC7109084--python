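import numpy as np
import pytest

from groovescope.protonation import assign_protonation, consensus_pka, net_charge
from groovescope.synthetic_data import make_pka_scenario, make_portal_scaffold


@pytest.fixture(scope="session")
def cd1d_scenario():
    return make_pka_scenario("CD1d_a1a2", seed=7)


@pytest.fixture(scope="session")
def scaffold14():
    return make_portal_scaffold(14.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def scenario_net_charge(name: str, ph: float, seed: int = 7) -> int:
    """End-to-end: scenario -> consensus -> protonation -> net charge."""
    _, table = make_pka_scenario(name, seed=seed)
    state = assign_protonation(consensus_pka(table), ph)
    return net_charge(state)
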
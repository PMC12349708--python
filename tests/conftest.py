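import numpy as np
import pytest

import v1micro as vm


@pytest.fixture(scope="session")
def tiny_network():
    """A 5%-scale control network, shared across tests (building and the
    first kernel compilation are the slow parts)."""
    sizes = vm.condition_sizes("pv", 3.5, 0.05)
    return vm.build_connectivity(sizes, seed=7)


@pytest.fixture(scope="session")
def tiny_record(tiny_network):
    """One 1-second trial of the 5%-scale control network."""
    cfg = vm.SimulationConfig(duration=1000.0, scale=0.05, n_trials=1)
    return vm.integrate_trial(tiny_network, cfg, trial_seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
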
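import numpy as np
import pytest

from shiftstim.network import ModuleSpec, NetworkSpec, build_network
from shiftstim.theory import STDPParams, DelaySpec


@pytest.fixture
def table_stdp() -> STDPParams:
    """Reference STDP window: stronger, narrower potentiation."""
    return STDPParams(A_plus=0.008, A_minus=0.005, tau_plus=10.0, tau_minus=20.0)


@pytest.fixture
def long_range_delays() -> DelaySpec:
    """Dendritic 0.5 ms + axonal 10.5 ms: total 11 ms, effective -10 ms."""
    return DelaySpec(tau_d=0.5, tau_a=10.5)


@pytest.fixture
def small_network():
    """Proportionally shrunk two-module network (20 neurons per module)."""
    spec = NetworkSpec(
        module_1=ModuleSpec(N=20),
        module_2=ModuleSpec(N=20),
        seed=7,
    )
    return build_network(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
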
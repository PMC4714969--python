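import numpy as np
import pytest

from ciliaphys.circuit import EquivalentCircuit
from ciliaphys.ephys import StepProtocol
from ciliaphys.synthetic import SimConfig


@pytest.fixture
def cfg():
    """Deterministic simulation config for tests."""
    return SimConfig(seed=1234)


@pytest.fixture
def hyperpol_protocol():
    """The standard capacitive-transient protocol: -80 -> -100 mV, 50 ms."""
    return StepProtocol(holding_mV=-80.0, step_mV=-20.0, t_on=0.01, t_off=0.06)


@pytest.fixture
def cell_circuit():
    """Whole-cell-like circuit: 20 pF reached through 18 MΩ."""
    return EquivalentCircuit(C_m=20.0, R_series=18.0)


@pytest.fixture
def cilium_circuit():
    """Whole-cilium-like circuit: 18.5 pF reached through 180 MΩ."""
    return EquivalentCircuit(C_m=18.5, R_series=180.0)
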
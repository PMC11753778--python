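import numpy as np
import pytest

from mcd import MCDParams
from mcd.experiments import simulate_step_design, synchrony_phase_curve


@pytest.fixture(scope="session")
def default_params():
    return MCDParams()


@pytest.fixture(scope="session")
def phase_curve():
    """Synchrony-vs-phase curve of the periodic design (40 shifts, 1 kHz)."""
    phases, curve = synchrony_phase_curve()
    return phases, curve


@pytest.fixture(scope="session")
def step_design():
    """Detector outputs for the full step design (4 conditions x 15 lags)."""
    return simulate_step_design(sample_rate=1000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
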
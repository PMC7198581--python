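import numpy as np
import pytest

from earpipe.synthdata import OscillatorParams, simulate_fluctuations


@pytest.fixture(scope="session")
def passive_recording():
    """60 s passive (T_eff = T) oscillator trace shared across tests."""
    return simulate_fluctuations(
        OscillatorParams(f0=250.0, Q=1.5, K=50e-6, T_eff=294.15, duration=60.0, seed=101)
    )


@pytest.fixture(scope="session")
def active_recording():
    """60 s active oscillator trace at T_eff = 5 T (power gain 4 k_BT)."""
    return simulate_fluctuations(
        OscillatorParams(
            f0=250.0, Q=1.5, K=50e-6, T_eff=5 * 294.15, duration=60.0, seed=202
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
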
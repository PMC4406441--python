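import numpy as np
import pytest

from optoburst import SimulationConfig, simulate_experiment
from optoburst.config import alternating_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return SimulationConfig()


@pytest.fixture
def quiet_config():
    """Noise-free, spontaneously silent culture for deterministic checks."""
    return SimulationConfig(noise_sigma=0.0, spontaneous_burst_rate=0.0)


@pytest.fixture(scope="session")
def straight_run():
    """One alternating-stimulation experiment on a symmetric device.

    Session-scoped: several test modules reuse this (moderately expensive)
    simulation read-only.
    """
    config = SimulationConfig()
    protocol = alternating_protocol(n_per_side=10)
    activity, recording = simulate_experiment(
        config, protocol, duration_ms=protocol.end + 5_000.0, seed=42
    )
    return config, activity, recording
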
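import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegssa as e

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def noise_series() -> e.TimeSeries:
    """Seeded broadband (white Gaussian) record, 8 s at 200 Hz."""
    return e.TimeSeries(np.random.default_rng(42).normal(size=1600), 200.0)


@pytest.fixture
def sinusoid_series() -> e.TimeSeries:
    """Pure 10.5 Hz sinusoid at a physiological 10 uV, 8 s at 200 Hz."""
    t = np.arange(1600) / 200.0
    return e.TimeSeries(10.0 * np.sin(2 * np.pi * 10.5 * t), 200.0)


@pytest.fixture(scope="session")
def spontaneous_sim() -> e.SimulatedEEG:
    """Artifact-free simulated record under the standard parameters."""
    return e.simulate_eeg(e.preset_config("spontaneous", seed=0))


@pytest.fixture(scope="session")
def full_sim() -> e.SimulatedEEG:
    """Simulated record with EOG, drift and white noise."""
    return e.simulate_eeg(e.preset_config("full", seed=0))
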
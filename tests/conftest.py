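import numpy as np
import pytest

from rescuephys.synth import SimRecordingParams, simulate_recording


@pytest.fixture(scope="session")
def sim_mixed():
    """A mid-sized recording with both states and spikes in each."""
    params = SimRecordingParams(
        duration_s=300.0,
        fs=500.0,
        spike_rate_wake=2.0,
        spike_rate_sleep=20.0,
        sleep_fraction=0.4,
        sleep_bout_s=20.0,
        seed=42,
    )
    return simulate_recording(params)


@pytest.fixture(scope="session")
def sim_wake_only():
    params = SimRecordingParams(
        duration_s=120.0,
        fs=500.0,
        spike_rate_wake=6.0,
        sleep_fraction=0.0,
        seed=7,
    )
    return simulate_recording(params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
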
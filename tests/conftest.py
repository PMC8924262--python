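import numpy as np
import pytest

from piezoquant.synthgen import (
    ChannelParams,
    GatingParams,
    PokingProtocol,
    PressureProtocol,
)

# compact protocols keep the replicate-heavy tests fast while preserving the
# acquisition characteristics (200 kHz / 2.9 kHz poking, 50 kHz pressure)
FAST_POKING = PokingProtocol(
    pre_stimulus_duration=20.0, hold_duration=120.0, post_stimulus_duration=10.0
)
FAST_PRESSURE = PressureProtocol(
    step_duration=1.0, pre_stimulus_duration=0.2, post_stimulus_duration=0.05
)


@pytest.fixture
def fast_poking() -> PokingProtocol:
    return FAST_POKING


@pytest.fixture
def fast_pressure() -> PressureProtocol:
    return FAST_PRESSURE


@pytest.fixture
def noiseless_gating() -> GatingParams:
    return GatingParams(noise_sd=0.0, leak=0.0)


@pytest.fixture
def single_channel() -> ChannelParams:
    return ChannelParams(n_channels=1, mean_open_dwell=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
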
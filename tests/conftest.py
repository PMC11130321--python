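import numpy as np
import pytest

from optomap import presets, synth


@pytest.fixture
def seal_membrane():
    return presets.SEAL_TEST_MEMBRANE


@pytest.fixture
def sag_25_300():
    """Sag preset with A = 25 pA, τ_h = 300 ms (closed-form slope ≈ 54.8)."""
    return synth.SagParams(amplitude_A=25.0, tau_h=300.0, enabled=True)


@pytest.fixture
def noise_free_sag_trace(seal_membrane, sag_25_300):
    return synth.simulate_voltage_clamp_step(seal_membrane, sag_25_300,
                                             noise_sd=0.0, seed=0)


def constant_rate_time(n, rate_khz=10.0):
    return np.arange(n) / rate_khz
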
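"""Simulator presets reproducing the study's recording conditions.

The group statistics behind these presets are the printed per-type values:
sag slope −3.1 ± 2.6 pA/s (n = 13) for LP-recipient L5 pyramidal cells,
82.5 ± 8.6 pA/s (n = 17) for ORBvl-recipient cells (mean ± SEM; the
population SD used here is SEM·√n), EPSC/IPSC onset latencies of
4.5 / 10.4 ms for LP inputs and 3.7 ms for ORBvl EPSCs, and the
regular- vs burst-spiking split of 29/44 burst cells.
"""
from __future__ import annotations

import numpy as np

from .synth import MembraneParams, SagParams, SpikingParams, SynapseParams

__all__ = [
    "SEAL_TEST_MEMBRANE", "CURRENT_CLAMP_MEMBRANE",
    "LP_SLOPE_MEAN", "LP_SLOPE_SD", "LP_N",
    "ORBVL_SLOPE_MEAN", "ORBVL_SLOPE_SD", "ORBVL_N",
    "LP_EPSC_LATENCY_MS", "LP_IPSC_LATENCY_MS", "ORBVL_EPSC_LATENCY_MS",
    "rs_spiking_preset", "bs_spiking_preset",
    "epsc_synapse", "ipsc_synapse",
    "sag_params_for_slope", "drift_params_for_slope",
    "V2M_LAYER_WEIGHTS",
]

# seal-test membrane: capacitance is the effective (compensated) value, so
# the capacitive transient (τ = Ra·Cm ≈ 0.3 ms) clears the 5 ms window point
SEAL_TEST_MEMBRANE = MembraneParams(
    membrane_resistance=150.0, membrane_capacitance=20.0,
    access_resistance=15.0)

# current-clamp membrane: anatomical capacitance, τ_m ≈ 22 ms
CURRENT_CLAMP_MEMBRANE = MembraneParams(
    membrane_resistance=150.0, membrane_capacitance=150.0,
    access_resistance=15.0)

# printed group statistics (population SD = SEM·√n)
LP_SLOPE_MEAN, LP_N = -3.1, 13
LP_SLOPE_SD = 2.6 * np.sqrt(LP_N)
ORBVL_SLOPE_MEAN, ORBVL_N = 82.5, 17
ORBVL_SLOPE_SD = 8.6 * np.sqrt(ORBVL_N)

LP_EPSC_LATENCY_MS = 4.5
LP_IPSC_LATENCY_MS = 10.4
ORBVL_EPSC_LATENCY_MS = 3.7

# depolarizing 500-ms steps in 25 pA increments around rheobase
_STEPS = tuple((amp, 500.0) for amp in (125.0, 150.0, 175.0, 200.0,
                                        225.0, 250.0))


def rs_spiking_preset() -> SpikingParams:
    """Regular-spiking phenotype: no DAP generator, strong slow adaptation
    keeps the near-threshold response to a single AP."""
    return SpikingParams(
        rheobase=190.0, threshold_v=-42.0, burst_enabled=False,
        dap_current_amp=0.0, dap_current_tau=20.0,
        step_sequence=_STEPS, adaptation_increment=80.0,
        adaptation_tau=400.0)


def bs_spiking_preset() -> SpikingParams:
    """Burst-spiking phenotype: a strong fast depolarizing after-current
    fires a spike doublet (first-pair rate > 100 Hz) and leaves a DAP."""
    return SpikingParams(
        rheobase=190.0, threshold_v=-42.0, burst_enabled=True,
        dap_current_amp=230.0, dap_current_tau=60.0,
        step_sequence=_STEPS, adaptation_increment=80.0,
        adaptation_tau=400.0)


def epsc_synapse(latency_ms: float = LP_EPSC_LATENCY_MS,
                 jitter_ms: float = 0.5,
                 peak_pa: float = -200.0,
                 noise_pa: float = 5.0) -> SynapseParams:
    """Inward light-evoked train (10 pulses at 10 Hz)."""
    return SynapseParams(onset_latency_mean=latency_ms,
                         onset_latency_sd=jitter_ms, rise_tau=1.0,
                         decay_tau=15.0, peak_amplitude=peak_pa,
                         n_pulses=10, pulse_rate=10.0, noise_sd=noise_pa)


def ipsc_synapse(latency_ms: float = LP_IPSC_LATENCY_MS,
                 jitter_ms: float = 1.0,
                 peak_pa: float = 200.0,
                 noise_pa: float = 5.0) -> SynapseParams:
    """Outward light-evoked train (multisynaptic inhibition)."""
    return SynapseParams(onset_latency_mean=latency_ms,
                         onset_latency_sd=jitter_ms, rise_tau=1.5,
                         decay_tau=20.0, peak_amplitude=peak_pa,
                         n_pulses=10, pulse_rate=10.0, noise_sd=noise_pa)


def sag_params_for_slope(target_slope: float, tau_h: float = 300.0,
                         drift_rate: float = 0.0) -> SagParams:
    """Sag amplitude whose closed-form window slope equals ``target_slope``.

    Inverts slope = A·(e^(−5/τ) − e^(−265/τ))/0.260 (plus drift).
    """
    gain = (np.exp(-5.0 / tau_h) - np.exp(-265.0 / tau_h)) / 0.260
    amp = (target_slope - drift_rate) / gain
    if amp < 0:
        raise ValueError("target slope below the drift component")
    return SagParams(amplitude_A=float(amp), tau_h=tau_h, enabled=True,
                     drift_rate=drift_rate)


def drift_params_for_slope(target_slope: float) -> SagParams:
    """Sag-free trace whose window slope is pure baseline drift."""
    return SagParams(enabled=False, drift_rate=float(target_slope))


# axon-profile preset emulating the medial-secondary-visual-cortex input
# pattern: 13% of mass in L1, 50% in L6, remainder spread over L2/3–L5
V2M_LAYER_WEIGHTS = {"L1": 0.13, "L2/3": 0.17, "L4": 0.10,
                     "L5": 0.10, "L6": 0.50}
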
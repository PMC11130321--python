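"""Seeded synthetic-data generators for every pipeline input.

This module produces voltage-clamp step sweeps with parameterizable sag
(I_h) currents, optogenetically evoked PSC trains, current-clamp spiking
sweeps (regular- and burst-spiking phenotypes), Patch-seq count matrices
with planted QC failures, and laminar axon-intensity profiles. Every
generator takes an explicit seed and stores its ground truth in trace or
matrix metadata, so downstream feature extractors can be validated without
any recorded data.

Units follow the package convention: ms, mV, pA, MΩ, pF, kHz, µm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import CurrentClampTrace, VoltageClampTrace

__all__ = [
    "MembraneParams",
    "SagParams",
    "SynapseParams",
    "SpikingParams",
    "CohortSpec",
    "PatchseqSpec",
    "analytic_sag_slope",
    "simulate_voltage_clamp_step",
    "simulate_psc_train",
    "simulate_current_clamp",
    "generate_patchseq_counts",
    "generate_axon_profile",
    "patchseq_fixture_v1",
    "DEFAULT_MARKER_PANELS",
]


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneParams:
    """Passive single-compartment parameters.

    ``membrane_capacitance`` is the *effective* capacitance seen by the
    voltage-clamp step, i.e. what remains after amplifier capacitance
    compensation. It sets the capacitive-transient time constant
    τ = Ra·Cm, which must decay well before the 5 ms point of the sag
    measurement window — exactly as on a compensated amplifier.
    """

    membrane_resistance: float          # MΩ (input resistance, Rin)
    membrane_capacitance: float         # pF (effective, compensated)
    access_resistance: float            # MΩ (Ra)
    resting_potential: float = -70.0    # mV
    holding_potential: float = -70.0    # mV

    def __post_init__(self) -> None:
        if self.membrane_resistance <= 0 or self.access_resistance <= 0:
            raise ValueError("resistances must be positive")
        if self.membrane_capacitance <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def transient_tau(self) -> float:
        """Capacitive-transient time constant, ms (MΩ·pF = µs)."""
        return self.access_resistance * self.membrane_capacitance / 1000.0

    @property
    def membrane_tau(self) -> float:
        """Membrane time constant Rm·Cm, ms."""
        return self.membrane_resistance * self.membrane_capacitance / 1000.0


@dataclass(frozen=True)
class SagParams:
    """Hyperpolarization-activated (HCN-mediated) sag current.

    The current activates as a single exponential from step onset,
    I_h(t) = A·(1 − e^(−t/τ_h)), which has the closed-form window slope
    used as the test oracle (:func:`analytic_sag_slope`). ``drift_rate``
    adds a linear baseline drift, the dominant nuisance in sag-free cells.
    """

    amplitude_A: float = 0.0    # pA, steady-state sag magnitude
    tau_h: float = 300.0        # ms, activation time constant
    enabled: bool = False
    drift_rate: float = 0.0     # pA/s linear baseline drift

    def __post_init__(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be nonnegative")


@dataclass(frozen=True)
class SynapseParams:
    """Light-evoked postsynaptic-current train parameters.

    ``peak_amplitude`` is signed: negative = inward (EPSC at −70 mV),
    positive = outward (IPSC at the excitatory reversal).
    """

    onset_latency_mean: float = 4.5   # ms after each light pulse
    onset_latency_sd: float = 0.5     # ms jitter, per pulse per trial
    rise_tau: float = 1.0             # ms
    decay_tau: float = 15.0           # ms
    peak_amplitude: float = -200.0    # pA, sign encodes polarity
    n_pulses: int = 10
    pulse_rate: float = 10.0          # Hz
    noise_sd: float = 5.0             # pA

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("require decay_tau > rise_tau > 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.onset_latency_mean < 0:
            raise ValueError("onset_latency_mean must be >= 0")

    @property
    def unit_peak_factor(self) -> float:
        """Peak of the unnormalized difference of exponentials."""
        tr, td = self.rise_tau, self.decay_tau
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        return float(np.exp(-t_peak / td) - np.exp(-t_peak / tr))

    @property
    def single_pulse_charge(self) -> float:
        """Analytic charge of one PSC, pC (signed)."""
        scale = self.peak_amplitude / self.unit_peak_factor
        return scale * (self.decay_tau - self.rise_tau) / 1000.0


@dataclass(frozen=True)
class SpikingParams:
    """Adaptive exponential integrate-and-fire parameters.

    ``dap_current_amp`` injects a decaying depolarizing current after each
    spike; large values reproduce the depolarizing afterpotential and the
    burst-spiking (BS) phenotype, zero gives regular spiking (RS).
    ``step_sequence`` amplitudes must increase so the near-threshold step
    (first step that fires) is well defined.
    """

    rheobase: float = 100.0             # pA, nominal
    threshold_v: float = -42.0          # mV, spike-initiation threshold
    burst_enabled: bool = False
    dap_current_amp: float = 0.0        # pA per spike
    dap_current_tau: float = 20.0       # ms
    step_sequence: tuple[tuple[float, float], ...] = ()
    delta_t: float = 0.8                # mV, spike-initiation sharpness
    adaptation_increment: float = 60.0  # pA per spike (RS stabilizer)
    adaptation_tau: float = 150.0       # ms

    def __post_init__(self) -> None:
        if self.dap_current_tau <= 0:
            raise ValueError("dap_current_tau must be positive")
        amps = [a for a, _ in self.step_sequence]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("step_sequence amplitudes must strictly increase")


@dataclass(frozen=True)
class CohortSpec:
    """How many cells of each class to simulate, and with what presets."""

    n_cells_per_class: dict[str, int]
    class_param_presets: dict[str, tuple[MembraneParams, SagParams,
                                         SynapseParams, SpikingParams]]
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_cells_per_class.items():
            if n < 0:
                raise ValueError("cell counts must be >= 0")
            if cls not in self.class_param_presets:
                raise ValueError(f"class {cls!r} has no parameter preset")


DEFAULT_MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "pan_neuronal": ("Actb", "Syt4", "Atp1a3", "Syt1", "Calm1", "Arpp21", "Snap25"),
    "excitatory": ("Gria2", "Camk2a", "Slc17a7"),
    "inhibitory": ("Slc32a1", "Gad1", "Gad2"),
    "glial": ("Adarb2", "Gfap", "Aqp4", "Mlc1"),
}


@dataclass(frozen=True)
class PatchseqSpec:
    """Blueprint for a synthetic Smart-seq2-style Patch-seq count matrix."""

    n_cells: int = 91
    n_genes: int = 2000
    class_labels: tuple[str, ...] | None = None  # per cell; None = alternate
    marker_panels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PANELS))
    n_low_depth_cells: int = 0      # library size forced below the QC floor
    n_contaminated_cells: int = 0   # inhibitory-marker sum forced above ceiling
    mean_detected_genes: dict[str, float] | None = None  # per class
    dispersion: float = 0.5         # NB size parameter (1/overdispersion)
    depth_floor: int = 500
    marker_ceiling: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low_depth_cells + self.n_contaminated_cells > self.n_cells:
            raise ValueError("planted failures exceed cell count")
        if min(self.n_cells, self.n_genes) < 0:
            raise ValueError("counts must be nonnegative")
        names: list[str] = []
        for panel in self.marker_panels.values():
            names.extend(panel)
        if len(set(names)) != len(names):
            raise ValueError("marker panels must be disjoint")


# ---------------------------------------------------------------------------
# Voltage clamp: step with sag
# ---------------------------------------------------------------------------

IH_WINDOW = (5.0, 265.0)   # ms from step onset, per the slope statistic
IH_WINDOW_S = 0.260        # window duration in seconds


def analytic_sag_slope(sag: SagParams) -> float:
    """Closed-form slope (pA/s) of the 5–265 ms window statistic.

    For I_h(t) = A·(1 − e^(−t/τ_h)) plus linear drift, the current change
    from 5 to 265 ms is A·(e^(−5/τ) − e^(−265/τ)) + drift·0.260, hence
    slope = A·(e^(−5/τ) − e^(−265/τ))/0.260 + drift_rate.
    """
    t0, t1 = IH_WINDOW
    slope = sag.drift_rate
    if sag.enabled:
        slope += (sag.amplitude_A
                  * (np.exp(-t0 / sag.tau_h) - np.exp(-t1 / sag.tau_h))
                  / IH_WINDOW_S)
    return float(slope)


def simulate_voltage_clamp_step(
    membrane: MembraneParams,
    sag: SagParams,
    step: tuple[float, float] = (-10.0, 300.0),
    sampling_rate: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
) -> VoltageClampTrace:
    """Simulate the −10 mV / 300 ms seal-test step used for Ra, Rin and I_h.

    The recorded current is the capacitive transient ΔI_transient = ΔV/Ra
    decaying with τ = Ra·Cm, the steady ohmic offset ΔI_steady = ΔV/Rin,
    the sag current (if enabled), linear drift, and Gaussian noise.
    Currents are relative to the holding current. The analytic window
    slope is stored in ``metadata["s_true"]``.
    """
    delta_v, duration = step
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if duration < IH_WINDOW[1]:
        raise ValueError(
            f"step duration {duration} ms is shorter than the "
            f"{IH_WINDOW[1]:g} ms measurement window")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    n = int(round((pre_ms + duration + post_ms) / dt)) + 1
    time = np.arange(n) * dt
    current = np.zeros(n)

    onset = pre_ms
    in_step = (time >= onset) & (time < onset + duration)
    rel = time[in_step] - onset

    di_steady = delta_v / membrane.membrane_resistance * 1000.0   # pA
    di_transient = delta_v / membrane.access_resistance * 1000.0  # pA
    tau_c = membrane.transient_tau

    i_step = di_steady + (di_transient - di_steady) * np.exp(-rel / tau_c)
    if sag.enabled:
        i_step = i_step + sag.amplitude_A * (1.0 - np.exp(-rel / sag.tau_h))
    i_step = i_step + sag.drift_rate * rel / 1000.0
    current[in_step] = i_step

    after = time >= onset + duration
    if np.any(after):
        rel2 = time[after] - (onset + duration)
        # symmetric capacitive off-transient back to holding
        current[after] = -di_transient * np.exp(-rel2 / tau_c)

    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n)

    return VoltageClampTrace(
        time=time,
        current=current,
        step_onset=onset,
        step_delta_v=delta_v,
        step_duration=duration,
        holding_potential=membrane.holding_potential,
        sampling_rate=sampling_rate,
        metadata={
            "s_true": analytic_sag_slope(sag),
            "di_transient_true": di_transient,
            "di_steady_true": di_steady,
            "ra_true": membrane.access_resistance,
            "rin_true": membrane.membrane_resistance,
            "sag_enabled": sag.enabled,
            "sag_amplitude": sag.amplitude_A,
            "sag_tau": sag.tau_h,
            "drift_rate": sag.drift_rate,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Voltage clamp: evoked PSC trains
# ---------------------------------------------------------------------------

def _psc_unit_waveform(t: np.ndarray, syn: SynapseParams) -> np.ndarray:
    """Difference of exponentials with unit peak, zero before t=0."""
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (np.exp(-tp / syn.decay_tau) - np.exp(-tp / syn.rise_tau))
    return out / syn.unit_peak_factor


def simulate_psc_train(
    syn: SynapseParams,
    pulse_times: list[float] | np.ndarray | None = None,
    sampling_rate: float = 10.0,
    n_trials: int = 1,
    seed: int | None = None,
    pre_ms: float = 100.0,
    post_ms: float = 400.0,
) -> list[VoltageClampTrace]:
    """Simulate light-train-evoked PSC sweeps (one trace per trial).

    Each light pulse is followed, after a per-pulse jittered latency, by a
    difference-of-exponentials current of the requested polarity. True
    onset times are stored per trial in ``metadata["true_onsets"]``.
    """
    if pulse_times is None:
        spacing = 1000.0 / syn.pulse_rate
        pulse_times = pre_ms + np.arange(syn.n_pulses) * spacing
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size == 0:
        raise ValueError("need at least one pulse")
    if np.any(np.diff(pulse_times) < 0) or np.any(pulse_times < 0):
        raise ValueError("pulse_times must be sorted and nonnegative")
    if np.any(np.diff(pulse_times) < syn.rise_tau):
        warnings.warn("pulses closer than rise_tau: responses will summate",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t_end = pulse_times[-1] + post_ms
    n = int(round(t_end / dt)) + 1
    time = np.arange(n) * dt
    scale = syn.peak_amplitude  # unit waveform already peak-normalized

    traces = []
    for trial in range(n_trials):
        current = np.zeros(n)
        onsets = []
        for pt in pulse_times:
            latency = syn.onset_latency_mean
            if syn.onset_latency_sd > 0:
                latency = max(0.0, latency + rng.normal(0.0, syn.onset_latency_sd))
            onset = pt + latency
            onsets.append(onset)
            if syn.peak_amplitude != 0:
                current += scale * _psc_unit_waveform(time - onset, syn)
        if syn.noise_sd > 0:
            current = current + rng.normal(0.0, syn.noise_sd, size=n)
        traces.append(VoltageClampTrace(
            time=time,
            current=current,
            step_onset=float(pulse_times[0]),
            step_delta_v=0.0,
            step_duration=None,
            sampling_rate=sampling_rate,
            metadata={
                "pulse_times": pulse_times.tolist(),
                "true_onsets": onsets,
                "true_latency_mean": syn.onset_latency_mean,
                "single_pulse_charge_pc": syn.single_pulse_charge,
                "polarity": "IPSC" if syn.peak_amplitude > 0 else "EPSC",
                "trial": trial,
                "seed": seed,
            },
        ))
    return traces


# ---------------------------------------------------------------------------
# Current clamp: adaptive exponential integrate-and-fire
# ---------------------------------------------------------------------------

_AP_PEAK_MV = 35.0       # stereotyped spike peak
_AHP_DROP_MV = 12.0      # fast AHP depth below threshold
_AP_RISE_MS = 0.4
_AP_FALL_MS = 0.6
_GAP_MS = 300.0          # zero-current gap between steps
_SPIKE_CUT_MV = -15.0    # integration cut: a spike has fired


def simulate_current_clamp(
    membrane: MembraneParams,
    spiking: SpikingParams,
    sampling_rate: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    pre_ms: float = 100.0,
) -> CurrentClampTrace:
    """Simulate a current-clamp step sequence with an adaptive exponential
    integrate-and-fire neuron.

    Subthreshold steps charge passively; suprathreshold steps spike via the
    exponential initiation term. After each spike a stereotyped AP waveform
    (rise to +35 mV, fall to a fast AHP) is pasted in, a depolarizing
    after-current (the DAP generator, if ``burst_enabled``) and an
    adaptation current are incremented, and integration resumes from the
    AHP. Ground-truth spike times per step and the resulting RS/BS mode
    are stored in metadata.
    """
    if not spiking.step_sequence:
        raise ValueError("step_sequence must be nonempty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate

    # build command-current waveform and step windows
    segments = [(0.0, pre_ms)]
    windows = []
    t_cursor = pre_ms
    for amp, dur in spiking.step_sequence:
        segments.append((amp, dur))
        windows.append((t_cursor, t_cursor + dur, amp))
        t_cursor += dur
        segments.append((0.0, _GAP_MS))
        t_cursor += _GAP_MS
    total = sum(d for _, d in segments)
    n = int(round(total / dt)) + 1
    time = np.arange(n) * dt
    inj = np.zeros(n)
    for start, stop, amp in windows:
        inj[(time >= start) & (time < stop)] = amp

    el = membrane.resting_potential
    rm = membrane.membrane_resistance
    tau_m = membrane.membrane_tau
    theta = spiking.threshold_v
    d_t = spiking.delta_t
    noise = (rng.normal(0.0, noise_sd, size=n) * np.sqrt(dt)
             if noise_sd > 0 else None)

    v = np.empty(n)
    v[0] = el
    i_dap = 0.0
    i_adapt = 0.0
    dap_decay = np.exp(-dt / spiking.dap_current_tau)
    adapt_decay = np.exp(-dt / spiking.adaptation_tau)
    spike_times: list[float] = []
    n_rise = max(1, int(round(_AP_RISE_MS / dt)))
    n_fall = max(1, int(round(_AP_FALL_MS / dt)))

    k = 0
    while k < n - 1:
        i_total = inj[k] + i_dap - i_adapt
        dv = (-(v[k] - el) + rm * i_total / 1000.0
              + d_t * np.exp((v[k] - theta) / d_t)) * dt / tau_m
        if noise is not None:
            dv += noise[k]
        v_next = v[k] + dv
        if v_next >= _SPIKE_CUT_MV:
            spike_times.append(time[k])
            v_ahp = theta - _AHP_DROP_MV
            # paste stereotyped AP: linear rise to peak, fall to fast AHP
            up_end = min(k + n_rise, n - 1)
            v[k:up_end + 1] = np.linspace(v[k], _AP_PEAK_MV, up_end - k + 1)
            dn_end = min(up_end + n_fall, n - 1)
            v[up_end:dn_end + 1] = np.linspace(_AP_PEAK_MV, v_ahp,
                                               dn_end - up_end + 1)
            if spiking.burst_enabled:
                # the after-current saturates: each spike restarts it at
                # its peak, so bursts terminate once adaptation builds up
                i_dap = spiking.dap_current_amp
            i_adapt += spiking.adaptation_increment
            i_dap *= dap_decay ** (dn_end - k)
            i_adapt *= adapt_decay ** (dn_end - k)
            k = dn_end
            if k >= n - 1:
                break
            continue
        v[k + 1] = v_next
        i_dap *= dap_decay
        i_adapt *= adapt_decay
        k += 1

    spike_arr = np.asarray(spike_times)
    spikes_per_step = []
    for start, stop, _amp in windows:
        sel = spike_arr[(spike_arr >= start) & (spike_arr < stop + 20.0)]
        spikes_per_step.append(sel.tolist())
    mode = None
    first_idx = None
    for idx, st in enumerate(spikes_per_step):
        if st:
            first_idx = idx
            mode = "BS" if len(st) >= 2 else "RS"
            break
    return CurrentClampTrace(
        time=time,
        voltage=v,
        injected_current=inj,
        sampling_rate=sampling_rate,
        metadata={
            "spike_times": spike_times,
            "spikes_per_step": spikes_per_step,
            "step_windows": [(s, e, a) for s, e, a in windows],
            "mode_true": mode,
            "near_threshold_step": first_idx,
            "threshold_v_true": theta,
            "burst_enabled": spiking.burst_enabled,
            "silent": len(spike_times) == 0,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Patch-seq count matrices
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float,
               shape: tuple[int, ...]) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and NB size ``size_param``."""
    mean = np.maximum(np.broadcast_to(mean, shape), 1e-12)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_patchseq_counts(spec: PatchseqSpec):
    """Generate a genes × cells count matrix with planted QC failures.

    Returns ``(CountMatrix, truth)`` where ``truth`` is a DataFrame with
    the true class label and planted QC fate per cell. Exactly
    ``spec.n_low_depth_cells`` cells have total counts below the depth
    floor, and exactly ``spec.n_contaminated_cells`` of the remaining
    cells have an inhibitory-marker log2(x+1) sum above the ceiling.
    """
    from .patchseq import CountMatrix  # local import to avoid a cycle

    marker_names = [g for panel in spec.marker_panels.values() for g in panel]
    if spec.n_genes < len(marker_names):
        raise ValueError("n_genes smaller than the union of marker panels")
    rng = np.random.default_rng(spec.seed)

    gene_names = marker_names + [
        f"Gene{i:05d}" for i in range(spec.n_genes - len(marker_names))]
    cell_ids = [f"cell{i:03d}" for i in range(spec.n_cells)]
    if spec.class_labels is not None:
        if len(spec.class_labels) != spec.n_cells:
            raise ValueError("class_labels length mismatch")
        labels = list(spec.class_labels)
    else:
        labels = ["LP" if i % 2 == 0 else "ORBvl" for i in range(spec.n_cells)]
    classes = sorted(set(labels))

    # baseline per-gene mean expression (shared across classes)
    base_mean = rng.lognormal(mean=0.7, sigma=1.0, size=spec.n_genes)
    # plant class-differential genes among the non-marker tail
    n_de = min(100, max(0, spec.n_genes - len(marker_names)) // 10)
    de_idx = len(marker_names) + np.arange(n_de)
    de_up_in = rng.choice(len(classes), size=n_de) if len(classes) > 1 else None

    class_mult = {c: np.ones(spec.n_genes) for c in classes}
    if de_up_in is not None and len(classes) == 2:
        for j, gi in enumerate(de_idx):
            class_mult[classes[de_up_in[j]]][gi] *= 6.0

    panel_rows = {name: [gene_names.index(g) for g in panel]
                  for name, panel in spec.marker_panels.items()}
    inh_rows = panel_rows.get("inhibitory", [])
    # marker baselines: neuronal/excitatory high, inhibitory & glial ~absent
    for name, rows in panel_rows.items():
        level = {"pan_neuronal": 80.0, "excitatory": 60.0,
                 "inhibitory": 0.02, "glial": 0.05}.get(name, 1.0)
        base_mean[rows] = level

    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    for j, lab in enumerate(labels):
        mu = base_mean * class_mult[lab]
        if spec.mean_detected_genes and lab in spec.mean_detected_genes:
            # thin detection down to the requested detected-gene count
            p_keep = min(1.0, spec.mean_detected_genes[lab] / spec.n_genes / 0.8)
            mask = rng.random(spec.n_genes) < p_keep
            mu = mu * mask
        counts[:, j] = _nb_counts(rng, mu, 1.0 / spec.dispersion,
                                  (spec.n_genes,))

    # choose planted-failure cells
    order = rng.permutation(spec.n_cells)
    low_idx = set(order[:spec.n_low_depth_cells].tolist())
    contam_idx = set(order[spec.n_low_depth_cells:
                           spec.n_low_depth_cells + spec.n_contaminated_cells]
                     .tolist())

    def inh_log2_sum(col: np.ndarray) -> float:
        return float(np.log2(col[inh_rows] + 1.0).sum())

    for j in range(spec.n_cells):
        col = counts[:, j]
        if j in contam_idx:
            # inflate the three inhibitory markers above the ceiling
            while inh_log2_sum(col) <= spec.marker_ceiling:
                col[inh_rows] = col[inh_rows] + rng.integers(8, 40,
                                                             len(inh_rows))
        else:
            # keep clean cells below the ceiling (rarely triggered)
            while inh_rows and inh_log2_sum(col) > spec.marker_ceiling:
                col[inh_rows] = col[inh_rows] // 2
        if j in low_idx:
            total_target = int(rng.integers(120, spec.depth_floor - 20))
            tot = col.sum()
            if tot > 0:
                col[:] = rng.multinomial(total_target, col / tot)
        else:
            # guarantee the complementary side of the floor
            while col.sum() < spec.depth_floor:
                col[0] += spec.depth_floor
        counts[:, j] = col

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_names, columns=cell_ids),
        labels=pd.Series(labels, index=cell_ids, name="cell_class"),
    )
    truth = pd.DataFrame({
        "cell_class": labels,
        "planted_low_depth": [j in low_idx for j in range(spec.n_cells)],
        "planted_contaminated": [j in contam_idx for j in range(spec.n_cells)],
    }, index=cell_ids)
    return matrix, truth


def patchseq_fixture_v1() -> PatchseqSpec:
    """The packaged 91-cell fixture: 4 low-depth and 7 contaminated cells
    planted (seed 7), so the two-stage QC passes exactly 80 cells."""
    labels = tuple("LP" if i % 2 == 0 else "ORBvl" for i in range(91))
    return PatchseqSpec(
        n_cells=91,
        n_genes=2000,
        class_labels=labels,
        n_low_depth_cells=4,
        n_contaminated_cells=7,
        mean_detected_genes={"LP": 3247.0, "ORBvl": 4013.0},
        seed=7,
    )


# ---------------------------------------------------------------------------
# Laminar axon-intensity profiles
# ---------------------------------------------------------------------------

def generate_axon_profile(
    layer_targets: dict[str, float],
    boundaries=None,
    smoothing_sd: float = 15.0,
    background: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    grid_um: float = 1.0,
):
    """Generate a depth-indexed fluorescence profile as a smoothed mixture
    of per-layer blocks plus constant background plus noise.

    ``layer_targets`` maps layer name → relative mass (integral) in that
    layer. True per-layer fractions are stored in profile metadata.
    """
    from scipy.ndimage import gaussian_filter1d

    from .circuit import DEFAULT_LAYER_TABLE
    from .profiles import AxonProfile

    table = boundaries if boundaries is not None else DEFAULT_LAYER_TABLE
    weights = {name: float(layer_targets.get(name, 0.0)) for name in table.names}
    if any(w < 0 for w in weights.values()):
        raise ValueError("layer weights must be >= 0")
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("at least one layer weight must be positive")

    rng = np.random.default_rng(seed)
    depth = np.arange(0.0, table.max_depth + grid_um / 2, grid_um)
    signal = np.zeros_like(depth)
    for name in table.names:
        upper, lower = table.interval(name)
        mask = (depth >= upper) & (depth < lower)
        width = lower - upper
        signal[mask] = weights[name] / width  # block height ∝ mass/width
    if smoothing_sd > 0:
        signal = gaussian_filter1d(signal, smoothing_sd / grid_um,
                                   mode="nearest")
    intensity = signal * 1000.0 + background
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=depth.size)

    true_fractions = {name: 100.0 * weights[name] / total_w
                      for name in table.names}
    return AxonProfile(
        depth=depth,
        intensity=intensity,
        background=background,
        layer_table=table,
        metadata={"true_fractions": true_fractions, "seed": seed,
                  "smoothing_sd": smoothing_sd},
    )
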
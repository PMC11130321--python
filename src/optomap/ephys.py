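"""Electrophysiological feature extraction from clamp traces.

Implements the measurement rules used throughout the pipeline: passive
properties from the −10 mV seal-test step (Ra = ΔV/ΔI_transient,
Rin = ΔV/ΔI_steady), the hyperpolarization-activated current statistic
(I_h slope = ΔI_5–265 / 0.260 s), evoked PSP/PSC metrics including charge
and onset latency, the inhibition fraction I/(I+E), the phase-plane
3×SD action-potential threshold, DAP amplitude, and RS/BS spiking-mode
classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .traces import CurrentClampTrace, VoltageClampTrace

__all__ = [
    "PassiveProperties",
    "IhMeasurement",
    "PSCMeasurement",
    "PSPMeasurement",
    "APFeatures",
    "SpikingClassification",
    "compute_passive_properties",
    "qc_recording",
    "compute_ih_slope",
    "measure_psp",
    "measure_psc",
    "inhibition_fraction",
    "detect_ap_threshold",
    "measure_dap",
    "classify_spiking_mode",
]

IH_WINDOW = (5.0, 265.0)    # ms from step onset
IH_WINDOW_S = 0.260         # s

RA_LIMIT_MOHM = 40.0
RA_MAX_REL_CHANGE = 0.20


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveProperties:
    Ra: float                 # MΩ
    Rin: float                # MΩ
    RMP: float | None = None  # mV

    def __post_init__(self) -> None:
        if self.Ra <= 0 or self.Rin <= 0:
            raise ValueError("resistances must be positive")


@dataclass(frozen=True)
class IhMeasurement:
    """Window statistic of the sag current: slope = ΔI_5–265 / 0.260 s."""

    slope: float                            # pA/s
    delta_i: float                          # pA
    window: tuple[float, float] = IH_WINDOW

    def __post_init__(self) -> None:
        if not np.isclose(self.slope * IH_WINDOW_S, self.delta_i,
                          rtol=1e-9, atol=1e-9):
            raise ValueError("slope must equal delta_i / 0.260 s")


@dataclass(frozen=True)
class PSCMeasurement:
    polarity: str                        # "EPSC" | "IPSC"
    peak_amplitude: float                # pA, signed
    charge: float                        # pC, signed
    onset_latencies: tuple[float | None, ...]  # ms per pulse, None=undetected
    n_trials_averaged: int
    baseline_charge_sd: float = 0.0      # pC, for response criteria

    @property
    def onset_latency(self) -> float | None:
        """Mean detected latency across pulses (None if none detected)."""
        found = [x for x in self.onset_latencies if x is not None]
        return float(np.mean(found)) if found else None


@dataclass(frozen=True)
class PSPMeasurement:
    amplitude: float         # mV, peak of trial average minus baseline
    activation_class: str    # none | activated | strong


@dataclass(frozen=True)
class SpikingClassification:
    mode: str | None                 # "RS" | "BS" | None (undefined)
    first_pair_rate: float | None    # Hz, defined iff >=2 spikes
    spike_times: tuple[float, ...]   # ms, at the near-threshold step
    step_index: int | None = None


@dataclass(frozen=True)
class APFeatures:
    threshold: float                      # mV
    dap_amplitude: float                  # mV, 0 when absent
    first_pair_rate: float | None         # Hz
    mode: str | None                      # RS | BS | None
    spike_times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.dap_amplitude < 0:
            raise ValueError("dap_amplitude must be >= 0")


# ---------------------------------------------------------------------------
# Passive properties and recording QC
# ---------------------------------------------------------------------------

def compute_passive_properties(
    trace: VoltageClampTrace,
    transient_window: float = 5.0,
    plateau_window: float = 50.0,
    baseline_window: float = 20.0,
) -> PassiveProperties:
    """Ra and Rin from a voltage step via Ohm's law.

    ΔI_transient is the extremum of the baseline-subtracted current within
    the first ``transient_window`` ms after step onset; ΔI_steady is the
    mean over the last ``plateau_window`` ms of the step. mV/pA = GΩ, so
    resistances are scaled ×1000 to MΩ.
    """
    if trace.step_duration is None or trace.step_delta_v == 0:
        raise ValueError("trace has no voltage step")
    onset = trace.step_onset
    if onset - trace.time[0] < baseline_window:
        raise ValueError(
            f"need >= {baseline_window} ms of pre-step baseline")
    i0 = trace.index_at(onset)
    base = float(np.mean(trace.current[trace.index_at(onset - baseline_window):i0]))

    i_tr_end = trace.index_at(onset + transient_window)
    seg = trace.current[i0:i_tr_end + 1] - base
    di_transient = seg[np.argmax(np.abs(seg))]

    step_end = onset + trace.step_duration
    j0 = trace.index_at(step_end - plateau_window)
    j1 = trace.index_at(step_end)
    di_steady = float(np.mean(trace.current[j0:j1])) - base

    ra = abs(trace.step_delta_v / di_transient) * 1000.0
    rin = abs(trace.step_delta_v / di_steady) * 1000.0
    rmp = trace.metadata.get("rmp")
    return PassiveProperties(Ra=ra, Rin=rin, RMP=rmp)


def qc_recording(
    ra_series: list[float],
    limit: float = RA_LIMIT_MOHM,
    max_rel_change: float = RA_MAX_REL_CHANGE,
) -> tuple[bool, str]:
    """Recording-stability check on repeated access-resistance readings.

    Fails if any Ra exceeds ``limit`` MΩ or the spread (max−min) exceeds
    ``max_rel_change`` of the first reading. Returns (passed, reason).
    """
    if len(ra_series) == 0:
        raise ValueError("empty Ra series")
    ra = np.asarray(ra_series, dtype=float)
    if np.any(ra > limit):
        return False, f"Ra exceeded {limit:g} MΩ (max {ra.max():g})"
    if len(ra) > 1:
        change = (ra.max() - ra.min()) / ra[0]
        if change > max_rel_change:
            return False, (f"Ra varied by {100 * change:.0f}% "
                           f"(> {100 * max_rel_change:.0f}%)")
    return True, "pass"


# ---------------------------------------------------------------------------
# I_h slope
# ---------------------------------------------------------------------------

def compute_ih_slope(trace: VoltageClampTrace,
                     smooth_window: float = 2.0) -> IhMeasurement:
    """Sag-current slope from the 5–265 ms window of the step.

    Endpoint currents are boxcar means over ``smooth_window`` ms centered
    on the 5 and 265 ms samples. Sag (a growing current during the step)
    yields a positive slope.
    """
    if trace.step_duration is None or trace.step_duration < IH_WINDOW[1]:
        raise ValueError("step shorter than the 265 ms measurement window")
    half = smooth_window / 2.0
    if trace.step_onset + IH_WINDOW[1] + half > trace.time[-1]:
        raise ValueError("measurement window exceeds the trace")

    def local_mean(t_center: float) -> float:
        a = trace.index_at(trace.step_onset + t_center - half)
        b = trace.index_at(trace.step_onset + t_center + half)
        return float(np.mean(trace.current[a:b + 1]))

    delta_i = local_mean(IH_WINDOW[1]) - local_mean(IH_WINDOW[0])
    return IhMeasurement(slope=delta_i / IH_WINDOW_S, delta_i=delta_i)


# ---------------------------------------------------------------------------
# Evoked PSP / PSC
# ---------------------------------------------------------------------------

def _average_trials(trials, attr: str) -> tuple[np.ndarray, np.ndarray, float]:
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    ref = trials[0]
    signals = []
    for tr in trials:
        if tr.time.shape != ref.time.shape or not np.allclose(tr.time, ref.time):
            raise ValueError("trials must share one time grid")
        signals.append(getattr(tr, attr))
    return ref.time, np.mean(signals, axis=0), ref.dt


def measure_psp(
    trials: list[CurrentClampTrace],
    stim_times: list[float] | np.ndarray,
    baseline_window: float = 50.0,
    response_window: float = 50.0,
) -> PSPMeasurement:
    """Trial-averaged evoked-PSP amplitude after the first light pulse.

    Trials are averaged pointwise first; amplitude is the maximum of
    (average − pre-stimulus baseline mean) within ``response_window`` ms
    after the first pulse.
    """
    from .circuit import classify_activation

    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("need at least one stimulus time")
    time, avg, _ = _average_trials(trials, "voltage")
    t1 = stim_times[0]
    if t1 - baseline_window < time[0] or t1 + response_window > time[-1]:
        raise ValueError("analysis windows fall outside the trace")
    if np.any((stim_times > t1 - baseline_window) & (stim_times < t1)):
        raise ValueError("baseline window overlaps a stimulus")
    base = np.mean(avg[(time >= t1 - baseline_window) & (time < t1)])
    resp = avg[(time > t1) & (time <= t1 + response_window)]
    amplitude = float(np.max(resp - base))
    return PSPMeasurement(amplitude=amplitude,
                          activation_class=classify_activation(amplitude))


def measure_psc(
    trials: list[VoltageClampTrace],
    pulse_times: list[float] | np.ndarray,
    polarity: str | None = None,
    baseline_window: float = 50.0,
    integration_window: float | None = None,
    onset_sd_multiplier: float = 3.0,
    onset_persistence_ms: float = 1.0,
    onset_search_ms: float = 50.0,
) -> PSCMeasurement:
    """Trial-averaged evoked-PSC peak, charge and per-pulse onset latency.

    Charge is the time integral of the baseline-subtracted average from
    light onset to ``integration_window`` ms after the last pulse
    (default 400 ms), in pC. Onset latency per pulse is the first time the
    average deviates from baseline by more than ``onset_sd_multiplier`` ×
    the baseline SD for at least ``onset_persistence_ms`` continuously.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size == 0:
        raise ValueError("need at least one pulse")
    time, avg, dt = _average_trials(trials, "current")
    t1 = pulse_times[0]
    if t1 - baseline_window < time[0]:
        raise ValueError("baseline window precedes the trace")
    base_mask = (time >= t1 - baseline_window) & (time < t1)
    base = float(np.mean(avg[base_mask]))
    base_sd = float(np.std(avg[base_mask]))
    signal = avg - base

    if integration_window is None:
        integration_window = 400.0
    int_end = min(pulse_times[-1] + integration_window, time[-1])
    int_mask = (time >= t1) & (time <= int_end)
    charge = float(np.trapezoid(signal[int_mask], time[int_mask]) / 1000.0)
    seg = signal[int_mask]
    peak = float(seg[np.argmax(np.abs(seg))]) if seg.size else 0.0
    if polarity is None:
        polarity = "IPSC" if peak > 0 else "EPSC"

    n_persist = max(1, int(round(onset_persistence_ms / dt)))
    latencies: list[float | None] = []
    for k, pt in enumerate(pulse_times):
        limit = pulse_times[k + 1] if k + 1 < len(pulse_times) \
            else pt + onset_search_ms
        limit = min(limit, pt + onset_search_ms, time[-1])
        mask = (time > pt) & (time <= limit)
        idx = np.where(mask)[0]
        if base_sd > 0:
            threshold = onset_sd_multiplier * base_sd
        else:
            # noiseless baseline: fall back to a 5%-of-peak floor so the
            # decaying tail of the previous response cannot trigger
            window_peak = np.abs(signal[idx]).max() if idx.size else 0.0
            if window_peak == 0:
                latencies.append(None)   # zero signal: onset undefined
                continue
            threshold = 0.05 * window_peak
        dev = np.abs(signal[idx]) > threshold
        onset = None
        run = 0
        for j, flag in enumerate(dev):
            run = run + 1 if flag else 0
            if run >= n_persist:
                onset = time[idx[j - n_persist + 1]] - pt
                break
        latencies.append(onset)

    # charge noise: per-sample noise integrated over the window plus the
    # (dominant) baseline-mean estimation error propagated over the window
    n_int = int(np.count_nonzero(int_mask))
    n_base = int(np.count_nonzero(base_mask))
    baseline_charge_sd = (base_sd * dt / 1000.0
                          * np.sqrt(n_int + n_int**2 / max(n_base, 1)))
    return PSCMeasurement(
        polarity=polarity,
        peak_amplitude=peak,
        charge=charge,
        onset_latencies=tuple(latencies),
        n_trials_averaged=len(trials),
        baseline_charge_sd=baseline_charge_sd,
    )


def inhibition_fraction(ipsc_charge: float, epsc_charge: float) -> float:
    """Inhibitory contribution I/(I+E) from charge magnitudes."""
    i, e = abs(ipsc_charge), abs(epsc_charge)
    if i == 0 and e == 0:
        raise ValueError("both charges are zero: fraction undefined")
    return i / (i + e)


# ---------------------------------------------------------------------------
# Action-potential features
# ---------------------------------------------------------------------------

def _spike_peaks(trace: CurrentClampTrace, height: float = -10.0) -> np.ndarray:
    peaks, _ = find_peaks(trace.voltage, height=height, distance=max(
        1, int(round(1.0 / trace.dt))))
    return peaks


def detect_ap_threshold(trace: CurrentClampTrace,
                        scan_start: float | None = None,
                        min_burn_in: int = 20,
                        smooth_ms: float = 0.5,
                        persist_ms: float = 0.2) -> float:
    """Phase-plane AP threshold by the 3×SD rule.

    For the first spike, dV/dt (lightly boxcar-smoothed over ``smooth_ms``)
    is scanned forward from ``scan_start`` (default: first injected-current
    onset). The threshold is the voltage at the first sample whose dV/dt
    exceeds three times the standard deviation of all preceding dV/dt
    samples since scan start — sustained for ``persist_ms`` so single noise
    excursions do not trigger — with a 20-sample burn-in before testing.
    """
    peaks = _spike_peaks(trace)
    if peaks.size == 0:
        raise ValueError("no spike in trace")
    if scan_start is None:
        nz = np.nonzero(trace.injected_current)[0]
        scan_start = trace.time[nz[0]] if nz.size else trace.time[0]
    i0 = trace.index_at(scan_start)
    first_peak = int(peaks[0])
    if first_peak - i0 < min_burn_in + 1:
        raise ValueError(f"fewer than {min_burn_in} samples precede the spike")
    dvdt = np.gradient(trace.voltage, trace.time)
    n_smooth = max(1, int(round(smooth_ms / trace.dt)))
    if n_smooth > 1:
        kernel = np.ones(n_smooth) / n_smooth
        dvdt = np.convolve(dvdt, kernel, mode="same")
    n_persist = max(1, int(round(persist_ms / trace.dt)))
    # running SD of the preceding samples via cumulative moments
    for k in range(i0 + min_burn_in, first_peak + 1):
        sd = float(np.std(dvdt[i0:k]))
        if sd > 0 and np.all(dvdt[k:min(k + n_persist, first_peak + 1)]
                             > 3.0 * sd):
            return float(trace.voltage[k])
    # fell through: report the voltage at the spike peak (conservative)
    return float(trace.voltage[first_peak])


def measure_dap(trace: CurrentClampTrace,
                single_spike_window: tuple[float, float],
                ahp_search_ms: float = 10.0,
                dap_search_ms: float = 80.0,
                min_prominence: float = 0.1) -> float:
    """Depolarizing-afterpotential amplitude after a single AP, mV.

    The fast-AHP minimum is located within ``ahp_search_ms`` after the
    spike peak; the DAP is the first subsequent local maximum minus that
    minimum, or 0 when the voltage decays monotonically (DAP absent).
    """
    t0, t1 = single_spike_window
    peaks = _spike_peaks(trace)
    peaks = peaks[(trace.time[peaks] >= t0) & (trace.time[peaks] <= t1)]
    if peaks.size != 1:
        raise ValueError(
            f"window must contain exactly one spike (found {peaks.size})")
    p = int(peaks[0])
    ahp_end = min(p + int(round(ahp_search_ms / trace.dt)),
                  trace.voltage.size - 1)
    ahp_idx = p + int(np.argmin(trace.voltage[p:ahp_end + 1]))
    v_ahp = trace.voltage[ahp_idx]
    search_end = min(ahp_idx + int(round(dap_search_ms / trace.dt)),
                     trace.voltage.size - 1)
    seg = trace.voltage[ahp_idx:search_end + 1]
    local_max, _ = find_peaks(seg, prominence=min_prominence)
    if local_max.size == 0:
        return 0.0
    return float(max(seg[local_max[0]] - v_ahp, 0.0))


def classify_spiking_mode(trace: CurrentClampTrace) -> SpikingClassification:
    """RS/BS classification at the near-threshold step.

    The near-threshold step is the first step of the sequence that elicits
    at least one spike: exactly one spike → RS; two or more → BS, with the
    instantaneous rate of the first pair = 1000 / first ISI (Hz).
    """
    windows = trace.metadata.get("step_windows")
    if windows is None:
        raise ValueError("trace metadata lacks step_windows")
    peaks = _spike_peaks(trace)
    spike_times = trace.time[peaks]
    for idx, (start, stop, _amp) in enumerate(windows):
        sel = spike_times[(spike_times >= start) & (spike_times < stop + 20.0)]
        if sel.size >= 1:
            if sel.size == 1:
                return SpikingClassification(
                    mode="RS", first_pair_rate=None,
                    spike_times=tuple(sel), step_index=idx)
            rate = 1000.0 / (sel[1] - sel[0])
            return SpikingClassification(
                mode="BS", first_pair_rate=float(rate),
                spike_times=tuple(sel), step_index=idx)
    return SpikingClassification(mode=None, first_pair_rate=None,
                                 spike_times=(), step_index=None)
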
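"""Feature-extraction tests: Ohm's-law recoveries, window statistics,
onset detection, AP features."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optomap import ephys, presets, synth
from optomap.traces import CurrentClampTrace, VoltageClampTrace


def make_step_trace(di_transient, di_steady, rate=10.0, onset=50.0,
                    duration=300.0, tau=0.3, post=50.0):
    """Analytic two-component step-response trace."""
    time = np.arange(int((onset + duration + post) * rate) + 1) / rate
    current = np.zeros_like(time)
    mask = (time >= onset) & (time < onset + duration)
    rel = time[mask] - onset
    current[mask] = di_steady + (di_transient - di_steady) * np.exp(-rel / tau)
    return VoltageClampTrace(time=time, current=current, step_onset=onset,
                             step_delta_v=-10.0, step_duration=duration,
                             sampling_rate=rate)


class TestPassiveProperties:
    def test_ohms_law_ra(self):
        trace = make_step_trace(-500.0, -100.0)
        props = ephys.compute_passive_properties(trace)
        assert props.Ra == pytest.approx(20.0, rel=0.01)

    def test_ohms_law_rin(self):
        trace = make_step_trace(-500.0, -100.0)
        props = ephys.compute_passive_properties(trace)
        assert props.Rin == pytest.approx(100.0, rel=0.01)

    def test_simulated_recovery_with_noise(self):
        membrane = synth.MembraneParams(membrane_resistance=150.0,
                                        membrane_capacitance=20.0,
                                        access_resistance=15.0)
        trace = synth.simulate_voltage_clamp_step(
            membrane, synth.SagParams(enabled=False), noise_sd=2.0, seed=3)
        props = ephys.compute_passive_properties(trace)
        assert props.Ra == pytest.approx(15.0, rel=0.10)
        assert props.Rin == pytest.approx(150.0, rel=0.10)

    def test_baseline_too_short_rejected(self):
        trace = make_step_trace(-500.0, -100.0, onset=10.0)
        with pytest.raises(ValueError, match="baseline"):
            ephys.compute_passive_properties(trace)


class TestRecordingQC:
    @pytest.mark.parametrize("series,expected", [
        ([25.0, 26.0, 25.0], True),
        ([45.0], False),              # exceeds the 40 MΩ limit
        ([20.0, 26.0], False),        # 30% change exceeds 20%
        ([40.0], True),               # at the limit, not over it
    ])
    def test_verdicts(self, series, expected):
        passed, _reason = ephys.qc_recording(series)
        assert passed is expected

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ephys.qc_recording([])


class TestIhSlope:
    def test_flat_current_zero_slope(self):
        trace = make_step_trace(-500.0, -100.0)
        assert ephys.compute_ih_slope(trace).slope == pytest.approx(0.0,
                                                                    abs=0.2)

    def test_linear_ramp_forced_by_formula(self):
        # I rises linearly from −10 pA at 5 ms to +16 pA at 265 ms
        rate, onset, dur = 10.0, 50.0, 300.0
        time = np.arange(int((onset + dur + 50) * rate) + 1) / rate
        current = np.zeros_like(time)
        mask = time >= onset
        current[mask] = -10.0 + (time[mask] - onset - 5.0) / 10.0
        trace = VoltageClampTrace(time=time, current=current, step_onset=onset,
                                  step_delta_v=-10.0, step_duration=dur,
                                  sampling_rate=rate)
        meas = ephys.compute_ih_slope(trace)
        assert meas.slope == pytest.approx(100.0, rel=1e-6)
        assert meas.delta_i == pytest.approx(26.0, rel=1e-6)

    def test_slope_delta_identity(self, noise_free_sag_trace):
        meas = ephys.compute_ih_slope(noise_free_sag_trace)
        assert meas.slope * 0.260 == pytest.approx(meas.delta_i, rel=1e-12)

    def test_noise_free_matches_closed_form_to_1e3(self, noise_free_sag_trace):
        est = ephys.compute_ih_slope(noise_free_sag_trace).slope
        assert est == pytest.approx(noise_free_sag_trace.metadata["s_true"],
                                    rel=1e-3)

    def test_short_step_rejected(self):
        trace = make_step_trace(-500.0, -100.0)
        trace.step_duration = 200.0
        with pytest.raises(ValueError):
            ephys.compute_ih_slope(trace)


def make_psp_trials(amplitude, n_trials=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rate, stim = 10.0, 100.0
    time = np.arange(int(300 * rate) + 1) / rate
    unit = np.exp(-time / 30.0) - np.exp(-time / 3.0)
    unit /= unit.max()   # peak-normalized PSP shape
    trials = []
    for _ in range(n_trials):
        v = np.full_like(time, -70.0)
        mask = time >= stim
        v[mask] += amplitude * unit[:mask.sum()]
        if noise:
            v = v + rng.normal(0, noise, time.size)
        trials.append(CurrentClampTrace(time=time, voltage=v,
                                        injected_current=np.zeros_like(time),
                                        sampling_rate=rate))
    return trials, [stim]


class TestMeasurePSP:
    def test_clean_deflection_recovered(self):
        trials, stims = make_psp_trials(5.0)   # programmed 5 mV peak
        meas = ephys.measure_psp(trials, stims)
        assert meas.amplitude == pytest.approx(5.0, abs=0.3)

    def test_zero_response(self):
        trials, stims = make_psp_trials(0.0)
        meas = ephys.measure_psp(trials, stims)
        assert meas.amplitude == pytest.approx(0.0, abs=1e-9)
        assert meas.activation_class == "none"

    def test_noisy_trials_recover_programmed_amplitude(self):
        trials, stims = make_psp_trials(8.0, n_trials=5, noise=0.5, seed=1)
        clean, _ = make_psp_trials(8.0, n_trials=1)
        expected = ephys.measure_psp(clean, stims).amplitude
        meas = ephys.measure_psp(trials, stims)
        assert meas.amplitude == pytest.approx(expected, rel=0.10)

    def test_trial_order_invariance(self):
        trials, stims = make_psp_trials(6.0, n_trials=4, noise=1.0, seed=2)
        a = ephys.measure_psp(trials, stims).amplitude
        b = ephys.measure_psp(trials[::-1], stims).amplitude
        assert a == b


class TestMeasurePSC:
    def test_flat_traces_zero_charge_no_onsets(self):
        rate = 10.0
        time = np.arange(int(600 * rate) + 1) / rate
        trace = VoltageClampTrace(time=time, current=np.zeros_like(time),
                                  step_onset=100.0, step_delta_v=0.0,
                                  sampling_rate=rate)
        meas = ephys.measure_psc([trace], [100.0])
        assert meas.charge == 0.0
        assert all(x is None for x in meas.onset_latencies)

    def test_rectangular_pulse_charge(self):
        rate = 10.0
        time = np.arange(int(600 * rate) + 1) / rate
        current = np.where((time >= 110.0) & (time < 120.0), 100.0, 0.0)
        trace = VoltageClampTrace(time=time, current=current, step_onset=100.0,
                                  step_delta_v=0.0, sampling_rate=rate)
        meas = ephys.measure_psc([trace], [100.0])
        # 100 pA × 10 ms = 1000 pA·ms = 1.0 pC
        assert meas.charge == pytest.approx(1.0, rel=0.02)

    def test_trial_order_invariance(self):
        syn = presets.epsc_synapse()
        trials = synth.simulate_psc_train(syn, n_trials=4, seed=7)
        pulses = trials[0].metadata["pulse_times"]
        a = ephys.measure_psc(trials, pulses)
        b = ephys.measure_psc(trials[::-1], pulses)
        assert a.charge == b.charge
        assert a.onset_latencies == b.onset_latencies

    def test_mean_latency_recovered_across_cells(self):
        rng = np.random.default_rng(0)
        detected = []
        for _ in range(20):
            lat = rng.normal(4.5, 0.5)
            syn = presets.epsc_synapse(lat, 0.1)
            trials = synth.simulate_psc_train(
                syn, n_trials=5, seed=int(rng.integers(2**31 - 1)))
            meas = ephys.measure_psc(trials, trials[0].metadata["pulse_times"])
            detected.append(meas.onset_latency)
        assert np.mean(detected) == pytest.approx(4.5, abs=0.3)


class TestInhibitionFraction:
    @pytest.mark.parametrize("i,e,expected", [
        (1.0, 0.0, 1.0),
        (2.0, 2.0, 0.5),
        (1.0, 3.0, 0.25),
    ])
    def test_examples(self, i, e, expected):
        assert ephys.inhibition_fraction(i, e) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            ephys.inhibition_fraction(0.0, 0.0)

    @given(i=st.floats(0.0, 1e4), e=st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_complementary(self, i, e):
        if i == 0 and e == 0:
            return
        f = ephys.inhibition_fraction(i, e)
        assert 0.0 <= f <= 1.0
        assert f + ephys.inhibition_fraction(e, i) == pytest.approx(1.0)


def make_spike_trace(threshold=-42.0, noise=0.1, seed=0, baseline=-48.0):
    """Flat (noisy) pre-spike baseline, then exponential upstroke starting
    at the programmed threshold, peak, and repolarization."""
    rng = np.random.default_rng(seed)
    rate = 20.0
    time = np.arange(int(100 * rate) + 1) / rate
    v = np.full_like(time, baseline)
    # slow approach to threshold then exponential blow-up
    ramp = (time >= 20.0) & (time < 60.0)
    v[ramp] = baseline + (threshold - baseline) * (time[ramp] - 20.0) / 40.0
    up = (time >= 60.0) & (time < 62.5)
    v[up] = threshold + 0.5 * (np.exp((time[up] - 60.0) / 0.35) - 1.0)
    peak_v = v[time < 62.5].max()
    down = (time >= 62.5) & (time < 64.0)
    v[down] = np.linspace(peak_v, -55.0, down.sum())
    v[time >= 64.0] = -55.0
    v = v + rng.normal(0, noise, time.size)
    inj = np.where(time >= 20.0, 100.0, 0.0)
    return CurrentClampTrace(time=time, voltage=v, injected_current=inj,
                             sampling_rate=rate)


class TestAPThreshold:
    def test_programmed_threshold_recovered(self):
        trace = make_spike_trace(threshold=-42.0, noise=0.1, seed=1)
        assert ephys.detect_ap_threshold(trace) == pytest.approx(-42.0,
                                                                 abs=2.0)

    def test_flat_trace_rejected(self):
        rate = 10.0
        time = np.arange(int(100 * rate) + 1) / rate
        trace = CurrentClampTrace(time=time, voltage=np.full_like(time, -70.0),
                                  injected_current=np.zeros_like(time),
                                  sampling_rate=rate)
        with pytest.raises(ValueError, match="no spike"):
            ephys.detect_ap_threshold(trace)

    def test_deterministic(self):
        trace = make_spike_trace(seed=2)
        assert ephys.detect_ap_threshold(trace) == ephys.detect_ap_threshold(
            trace)


def make_dap_trace(dap_amplitude):
    """Single stereotyped spike, fast AHP to −55 mV, then an optional
    rebound hump of the requested amplitude before decay."""
    rate = 10.0
    time = np.arange(int(200 * rate) + 1) / rate
    v = np.full_like(time, -70.0)
    up = (time >= 50.0) & (time < 51.0)
    v[up] = np.linspace(-45.0, 30.0, up.sum())
    dn = (time >= 51.0) & (time < 53.0)
    v[dn] = np.linspace(30.0, -55.0, dn.sum())
    after = time >= 53.0
    rel = time[after] - 53.0
    hump = dap_amplitude * (np.exp(-rel / 30.0) - np.exp(-rel / 3.0)) / 0.774
    v[after] = -55.0 + hump - rel * 0.02
    return CurrentClampTrace(time=time, voltage=v,
                             injected_current=np.zeros_like(time),
                             sampling_rate=rate)


class TestDAP:
    def test_monotonic_decay_reports_zero(self):
        trace = make_dap_trace(0.0)
        assert ephys.measure_dap(trace, (40.0, 120.0)) == 0.0

    def test_rebound_amplitude_measured(self):
        trace = make_dap_trace(5.0)
        assert ephys.measure_dap(trace, (40.0, 120.0)) == pytest.approx(
            5.0, abs=0.8)

    def test_bs_preset_has_larger_dap_than_rs(self):
        import dataclasses

        daps = {}
        for name, preset in [("RS", presets.rs_spiking_preset()),
                             ("BS", presets.bs_spiking_preset())]:
            sp = dataclasses.replace(preset, step_sequence=((900.0, 6.0),))
            trace = synth.simulate_current_clamp(
                presets.CURRENT_CLAMP_MEMBRANE, sp, noise_sd=0.05, seed=3)
            start = trace.metadata["step_windows"][0][0]
            daps[name] = ephys.measure_dap(trace, (start, start + 100.0))
        assert daps["BS"] > daps["RS"]
        assert daps["RS"] == 0.0

    def test_multiple_spikes_rejected(self):
        trace = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                             presets.bs_spiking_preset(),
                                             noise_sd=0.1, seed=4)
        with pytest.raises(ValueError, match="exactly one"):
            ephys.measure_dap(trace, (0.0, trace.time[-1]))


class TestSpikingMode:
    def _trace_with_spikes(self, spike_times):
        rate = 10.0
        time = np.arange(int(800 * rate) + 1) / rate
        v = np.full_like(time, -70.0)
        for ts in spike_times:
            up = (time >= ts) & (time < ts + 0.5)
            v[up] = np.linspace(-45.0, 30.0, up.sum())
            dn = (time >= ts + 0.5) & (time < ts + 1.5)
            v[dn] = np.linspace(30.0, -55.0, dn.sum())
        inj = np.where((time >= 80.0) & (time < 580.0), 150.0, 0.0)
        return CurrentClampTrace(
            time=time, voltage=v, injected_current=inj, sampling_rate=rate,
            metadata={"step_windows": [(80.0, 580.0, 150.0)]})

    def test_single_spike_is_rs(self):
        cls = ephys.classify_spiking_mode(self._trace_with_spikes([100.0]))
        assert cls.mode == "RS"
        assert cls.first_pair_rate is None

    def test_spike_complex_is_bs_with_first_pair_rate(self):
        cls = ephys.classify_spiking_mode(
            self._trace_with_spikes([100.0, 105.0, 180.0]))
        assert cls.mode == "BS"
        assert cls.first_pair_rate == pytest.approx(200.0, rel=0.05)

    def test_no_spiking_step_undefined(self):
        cls = ephys.classify_spiking_mode(self._trace_with_spikes([]))
        assert cls.mode is None
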
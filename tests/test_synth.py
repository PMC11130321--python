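"""Synthetic-data generator tests: closed-form oracles, determinism,
planted-structure guarantees."""
import numpy as np
import pytest

from optomap import ephys, presets, synth
from optomap.profiles import layer_fractions, subtract_background

# closed form evaluated independently: 25·(e^(−5/300) − e^(−265/300))/0.260
EXPECTED_SLOPE_A25_TAU300 = 25.0 * (np.exp(-5 / 300) - np.exp(-265 / 300)) / 0.260


class TestVoltageClampStep:
    def test_no_sag_no_drift_gives_zero_slope(self, seal_membrane):
        trace = synth.simulate_voltage_clamp_step(
            seal_membrane, synth.SagParams(enabled=False), noise_sd=0.0, seed=0)
        assert abs(ephys.compute_ih_slope(trace).slope) < 0.1

    def test_closed_form_sag_slope(self, noise_free_sag_trace):
        assert noise_free_sag_trace.metadata["s_true"] == pytest.approx(
            EXPECTED_SLOPE_A25_TAU300, rel=1e-12)
        est = ephys.compute_ih_slope(noise_free_sag_trace).slope
        assert est == pytest.approx(EXPECTED_SLOPE_A25_TAU300, rel=0.01)

    def test_transient_peak_follows_ohms_law(self):
        membrane = synth.MembraneParams(membrane_resistance=150.0,
                                        membrane_capacitance=20.0,
                                        access_resistance=20.0)
        trace = synth.simulate_voltage_clamp_step(
            membrane, synth.SagParams(enabled=False), noise_sd=0.0, seed=0)
        # ΔV = −10 mV across Ra = 20 MΩ → −500 pA transient
        assert np.min(trace.current) == pytest.approx(-500.0, rel=0.01)

    def test_slope_monotone_in_sag_amplitude(self, seal_membrane):
        slopes = []
        for amp in (5.0, 15.0, 40.0, 90.0):
            sag = synth.SagParams(amplitude_A=amp, tau_h=300.0, enabled=True)
            trace = synth.simulate_voltage_clamp_step(seal_membrane, sag,
                                                      noise_sd=0.0, seed=0)
            slopes.append(ephys.compute_ih_slope(trace).slope)
        assert np.all(np.diff(slopes) > 0)

    def test_drift_recovered_exactly(self, seal_membrane):
        sag = synth.SagParams(enabled=False, drift_rate=-3.1)
        trace = synth.simulate_voltage_clamp_step(seal_membrane, sag,
                                                  noise_sd=0.0, seed=0)
        assert ephys.compute_ih_slope(trace).slope == pytest.approx(-3.1,
                                                                    abs=0.05)

    def test_seed_determinism(self, seal_membrane, sag_25_300):
        a = synth.simulate_voltage_clamp_step(seal_membrane, sag_25_300,
                                              noise_sd=5.0, seed=11)
        b = synth.simulate_voltage_clamp_step(seal_membrane, sag_25_300,
                                              noise_sd=5.0, seed=11)
        assert np.array_equal(a.current, b.current)

    @pytest.mark.parametrize("kwargs", [
        {"sampling_rate": 0.0},
        {"step": (-10.0, 200.0)},     # shorter than the 265 ms window
    ])
    def test_invalid_protocols_rejected(self, seal_membrane, kwargs):
        with pytest.raises(ValueError):
            synth.simulate_voltage_clamp_step(
                seal_membrane, synth.SagParams(enabled=False), **kwargs)


class TestPSCTrain:
    def test_zero_amplitude_gives_noise_only(self):
        syn = synth.SynapseParams(peak_amplitude=0.0, noise_sd=0.0)
        trace = synth.simulate_psc_train(syn, seed=0)[0]
        assert np.allclose(trace.current, 0.0)

    def test_programmed_latency_exact_without_jitter(self):
        syn = synth.SynapseParams(onset_latency_mean=4.5, onset_latency_sd=0.0,
                                  peak_amplitude=-200.0, noise_sd=0.0)
        trace = synth.simulate_psc_train(syn, seed=0)[0]
        meas = ephys.measure_psc([trace], trace.metadata["pulse_times"])
        for lat in meas.onset_latencies:
            assert lat == pytest.approx(4.5, abs=0.11)  # one-sample grid

    def test_train_charge_matches_per_pulse_sum(self):
        syn = synth.SynapseParams(onset_latency_mean=4.5, onset_latency_sd=0.0,
                                  rise_tau=1.0, decay_tau=20.0,
                                  peak_amplitude=-200.0, noise_sd=0.0)
        trace = synth.simulate_psc_train(syn, seed=0)[0]
        meas = ephys.measure_psc([trace], trace.metadata["pulse_times"])
        expected = 10 * trace.metadata["single_pulse_charge_pc"]
        assert meas.charge == pytest.approx(expected, rel=0.05)

    def test_close_pulses_warn_but_simulate(self):
        syn = synth.SynapseParams(rise_tau=2.0, decay_tau=10.0,
                                  peak_amplitude=-100.0, noise_sd=0.0)
        with pytest.warns(UserWarning, match="summate"):
            traces = synth.simulate_psc_train(syn, pulse_times=[50.0, 51.0],
                                              seed=0)
        assert len(traces) == 1

    def test_seed_determinism_across_trials(self):
        syn = presets.epsc_synapse()
        a = synth.simulate_psc_train(syn, n_trials=3, seed=4)
        b = synth.simulate_psc_train(syn, n_trials=3, seed=4)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.current, tb.current)


class TestCurrentClamp:
    def test_subthreshold_steps_silent(self):
        spiking = synth.SpikingParams(
            step_sequence=((25.0, 500.0), (50.0, 500.0)))
        trace = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                             spiking, seed=0)
        assert trace.metadata["silent"]
        assert trace.metadata["mode_true"] is None

    def test_large_dap_fires_fast_doublet(self):
        import dataclasses

        spiking = dataclasses.replace(presets.bs_spiking_preset(),
                                      dap_current_amp=600.0)
        trace = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                             spiking, noise_sd=0.1, seed=1)
        cls = ephys.classify_spiking_mode(trace)
        assert cls.mode == "BS"
        assert cls.first_pair_rate > 100.0

    def test_burst_disabled_gives_single_spike_rs(self):
        trace = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                             presets.rs_spiking_preset(),
                                             noise_sd=0.1, seed=2)
        cls = ephys.classify_spiking_mode(trace)
        assert cls.mode == "RS"
        assert len(cls.spike_times) == 1

    def test_empty_step_sequence_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                         synth.SpikingParams(), seed=0)

    def test_seed_determinism(self):
        a = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                         presets.bs_spiking_preset(),
                                         noise_sd=0.2, seed=9)
        b = synth.simulate_current_clamp(presets.CURRENT_CLAMP_MEMBRANE,
                                         presets.bs_spiking_preset(),
                                         noise_sd=0.2, seed=9)
        assert np.array_equal(a.voltage, b.voltage)


class TestPatchseqCounts:
    def test_no_planted_failures_all_pass(self):
        from optomap.patchseq import qc_cells

        spec = synth.PatchseqSpec(n_cells=20, n_genes=200, seed=1)
        matrix, _ = synth.generate_patchseq_counts(spec)
        assert qc_cells(matrix).n_pass == 20

    def test_fixture_91_cells_pass_80(self):
        from optomap.patchseq import qc_cells

        matrix, truth = synth.generate_patchseq_counts(
            synth.patchseq_fixture_v1())
        report = qc_cells(matrix)
        assert report.n_pass == 80
        assert truth["planted_low_depth"].sum() == 4
        assert truth["planted_contaminated"].sum() == 7

    def test_determinism(self):
        spec = synth.patchseq_fixture_v1()
        m1, _ = synth.generate_patchseq_counts(spec)
        m2, _ = synth.generate_patchseq_counts(spec)
        assert m1.counts.equals(m2.counts)

    def test_infeasible_spec_rejected(self):
        spec = synth.PatchseqSpec(n_cells=5, n_genes=10, seed=0)
        with pytest.raises(ValueError, match="marker"):
            synth.generate_patchseq_counts(spec)


class TestAxonProfileGenerator:
    def test_single_layer_mass_concentrates(self):
        profile = synth.generate_axon_profile({"L6": 1.0}, smoothing_sd=5.0,
                                              background=2.0, seed=0)
        fractions = layer_fractions(subtract_background(profile, 2.0))
        assert fractions["L6"] >= 95.0

    def test_equal_weights_equal_width_layers(self):
        from optomap.circuit import LayerTable

        table = LayerTable(names=("A", "B", "C", "D"),
                           bounds=(0.0, 100.0, 200.0, 300.0, 400.0))
        profile = synth.generate_axon_profile(
            {"A": 1, "B": 1, "C": 1, "D": 1}, boundaries=table,
            smoothing_sd=0.0, background=0.0, seed=0)
        fractions = layer_fractions(profile, table)
        for v in fractions.values():
            assert v == pytest.approx(25.0, abs=0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_axon_profile({"L1": 0.0}, seed=0)

    def test_v2m_preset_fractions_recovered(self):
        profile = synth.generate_axon_profile(presets.V2M_LAYER_WEIGHTS,
                                              smoothing_sd=10.0,
                                              background=5.0, noise_sd=0.2,
                                              seed=3)
        fractions = layer_fractions(subtract_background(profile, 5.0))
        truth = profile.metadata["true_fractions"]
        assert truth["L1"] == pytest.approx(13.0)
        assert truth["L6"] == pytest.approx(50.0)
        for name in truth:
            assert fractions[name] == pytest.approx(truth[name], abs=3.0)

    def test_determinism(self):
        a = synth.generate_axon_profile(presets.V2M_LAYER_WEIGHTS,
                                        noise_sd=1.0, seed=5)
        b = synth.generate_axon_profile(presets.V2M_LAYER_WEIGHTS,
                                        noise_sd=1.0, seed=5)
        assert np.array_equal(a.intensity, b.intensity)
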
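import numpy as np
import pytest
from scipy import signal as sps

from ultracoll import synthetic_data as sd
from ultracoll.signal_io import ParameterError, StimulusEvent, UnitSpikes


class TestTonePip:
    def test_shape_and_ramp_endpoints(self):
        w = sd.make_tone_pip(20.0, 80.0, 50.0, 2.0, 192000.0)
        assert w.size == 9600
        assert w[0] == 0.0 and w[-1] == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_rms(self):
        w = sd.make_tone_pip(20.0, 80.0, 50.0, 2.0, 192000.0)
        fs = 192000.0
        core = w[int(0.005 * fs) : int(0.045 * fs)]
        amp = sd.level_to_amplitude(80.0)
        assert np.sqrt(np.mean(core**2)) == pytest.approx(amp / np.sqrt(2), rel=1e-3)

    def test_nyquist_violation(self):
        with pytest.raises(ParameterError):
            sd.make_tone_pip(100.0, 80.0, 50.0, 2.0, 192000.0)


class TestCallSynthesis:
    def test_constant_frequency_call(self):
        spec = sd.CallSpec("c", 40.0, 70.0, 70.0, 80.0)
        w = sd.make_call(spec, 250000.0)
        assert w.size == int(round(0.040 * 250000))
        f, t, S = sps.spectrogram(w, fs=250000.0, nperseg=1024)
        peak = f[np.argmax(S.mean(axis=1))]
        assert peak == pytest.approx(70000.0, abs=1000.0)

    def test_sweep_endpoint_frequencies(self):
        spec = sd.CallSpec("c", 50.0, 62.0, 88.0, 90.0)
        w = sd.make_call(spec, 250000.0)
        f, t, S = sps.spectrogram(w, fs=250000.0, nperseg=512, noverlap=256)
        f_at_start = f[np.argmax(S[:, 1])] / 1000.0
        f_at_end = f[np.argmax(S[:, -2])] / 1000.0
        assert f_at_start == pytest.approx(62.0, abs=2.0)
        assert f_at_end == pytest.approx(88.0, abs=2.0)

    def test_band_violation(self):
        with pytest.raises(ParameterError):
            sd.CallSpec("c", 40.0, 70.0, 95.0, 80.0)

    def test_energy_confined_to_call_band(self):
        spec = sd.CallSpec("c", 40.0, 65.0, 85.0, 80.0, am_depth=0.3)
        w = sd.make_call(spec, 250000.0)
        f, P = sps.periodogram(w, fs=250000.0)
        inband = P[(f >= 55000) & (f <= 95000)].sum()
        assert inband / P.sum() > 0.99


class TestRateFunction:
    def test_tone_at_cf_above_threshold_drives(self):
        n = sd.NeuronSpec(cf_khz=25.0, threshold_db=35.0)
        ev = StimulusEvent(0.0, "tone", 65.0, 50.0, freq_khz=25.0)
        _, r = sd.rate_function(n, ev)
        assert r.max() > n.spont_rate_hz + 100.0

    def test_far_off_cf_low_level_is_spontaneous(self):
        n = sd.NeuronSpec(cf_khz=25.0, threshold_db=35.0)
        ev = StimulusEvent(0.0, "tone", 15.0, 50.0, freq_khz=200.0)
        _, r = sd.rate_function(n, ev)
        assert np.allclose(r, n.spont_rate_hz)

    def test_onset_class_returns_to_spont_within_10ms(self):
        n = sd.NeuronSpec(cf_khz=25.0, psth_class="onset", fsl_ms=2.0)
        ev = StimulusEvent(0.0, "tone", 65.0, 50.0, freq_khz=25.0)
        t, r = sd.rate_function(n, ev)
        late = r[(t > n.fsl_ms + 10.0) & (t < 50.0)]
        assert np.all(late < n.spont_rate_hz + 0.02 * n.max_rate_hz)

    def test_call_drive_predicate(self):
        call = sd.CallSpec("c", 40.0, 70.0, 80.0, 80.0)
        high = sd.NeuronSpec(cf_khz=75.0, threshold_db=40.0)
        low = sd.NeuronSpec(cf_khz=20.0, threshold_db=40.0)
        assert sd.call_drives(high, call)
        assert not sd.call_drives(low, call)
        t, r = sd.rate_function(high, call)
        assert r.max() > high.spont_rate_hz + 50.0


class TestSpikeTrainSimulation:
    def test_poisson_limit_count_and_cv(self):
        t = np.arange(0.0, 100_000.0 + 1, 1.0)
        r = np.full_like(t, 100.0)
        st = sd.simulate_spike_train(t, r, gamma_order=1.0, seed=1)
        assert abs(st.size - 10_000) < 3 * np.sqrt(10_000)
        isi = np.diff(st)
        assert np.std(isi, ddof=1) / np.mean(isi) == pytest.approx(1.0, abs=0.05)

    def test_gamma_order_4_halves_cv(self):
        t = np.arange(0.0, 100_000.0 + 1, 1.0)
        r = np.full_like(t, 100.0)
        st = sd.simulate_spike_train(t, r, gamma_order=4.0, seed=2)
        isi = np.diff(st)
        assert np.std(isi, ddof=1) / np.mean(isi) == pytest.approx(0.5, abs=0.05)

    def test_zero_rate_gives_empty_train(self):
        t = np.arange(0.0, 1000.0, 1.0)
        assert sd.simulate_spike_train(t, np.zeros_like(t), seed=3).size == 0

    def test_refractory_period_enforced(self):
        t = np.arange(0.0, 20_000.0, 0.5)
        r = np.full_like(t, 200.0)
        st = sd.simulate_spike_train(t, r, gamma_order=1.0, refractory_ms=1.0, seed=4)
        assert np.diff(st).min() >= 1.0

    def test_negative_rate_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ParameterError):
            sd.simulate_spike_train(t, np.full_like(t, -1.0))

    def test_reproducible_under_seed(self):
        t = np.arange(0.0, 5000.0, 1.0)
        r = np.full_like(t, 50.0)
        a = sd.simulate_spike_train(t, r, gamma_order=2.0, refractory_ms=0.5, seed=9)
        b = sd.simulate_spike_train(t, r, gamma_order=2.0, refractory_ms=0.5, seed=9)
        assert np.array_equal(a, b)


class TestRenderTrace:
    def test_single_spike_reproduces_template(self):
        fs = 24414.0
        tmpl = sd.biphasic_template(fs)
        u = UnitSpikes("u1", "a", "AN", np.array([10.0]), source="simulated")
        tr = sd.render_trace([u], {"u1": tmpl}, noise_sd=0.0, sample_rate_hz=fs, duration_ms=30.0)
        i0 = int(round(10.0 / 1000.0 * fs))
        np.testing.assert_allclose(tr.samples[0, i0 : i0 + tmpl.size], tmpl)
        assert np.all(tr.samples[0, : i0] == 0.0)

    def test_pure_noise_sd(self):
        tr = sd.render_trace([], {}, noise_sd=1e-4, sample_rate_hz=24414.0, duration_ms=2000.0, seed=5)
        assert tr.samples.std() == pytest.approx(1e-4, rel=0.05)

    def test_gain_linearity(self):
        fs = 24414.0
        tmpl = sd.biphasic_template(fs)
        u = UnitSpikes("u1", "a", "AN", np.array([5.0, 12.0]), source="simulated")
        one = sd.render_trace([u], {"u1": tmpl}, 0.0, fs, duration_ms=20.0)
        two = sd.render_trace([u], {"u1": tmpl}, 0.0, fs, duration_ms=20.0, gains={"u1": 2.0})
        np.testing.assert_allclose(two.samples, 2.0 * one.samples)


class TestSimulateABR:
    def test_noiseless_wave_v_amplitude(self):
        spec = sd.ABRSpec(noise_sd_uv=0.0, n_sweeps=4)
        spec.waveV_amp_vs_freq[64] = 1.2
        sweeps = sd.simulate_abr(spec, 64, seed=0)
        avg = sweeps.mean(axis=0)
        t = np.arange(avg.size) / spec.sample_rate_hz * 1000.0
        band = (t >= 4.5) & (t <= 7.0)
        i_peak = np.nonzero(band)[0][np.argmax(avg[band])]
        assert t[i_peak] == pytest.approx(5.7, abs=0.05)
        trough = avg[: i_peak][np.nonzero(
            (avg[1:i_peak] < avg[: i_peak - 1]) & (avg[1:i_peak] <= avg[2 : i_peak + 1])
        )[0][-1] + 1]
        assert avg[i_peak] - trough == pytest.approx(1.2, rel=0.02)

    def test_zero_amplitude_maps_give_null_waveform(self):
        spec = sd.ABRSpec(
            waveI_amp_vs_freq={64: 0.0},
            waveV_amp_vs_freq={64: 0.0},
            mid_wave_amps_uv=(0.0, 0.0, 0.0),
            noise_sd_uv=1.0,
            n_sweeps=500,
        )
        avg = sd.simulate_abr(spec, 64, seed=1).mean(axis=0)
        se = 1.0 / np.sqrt(500)
        assert np.abs(avg.mean()) < 3 * se

    def test_averaging_reduces_noise_sd_by_sqrt_n(self):
        spec = sd.ABRSpec(
            waveI_amp_vs_freq={64: 0.0},
            waveV_amp_vs_freq={64: 0.0},
            mid_wave_amps_uv=(0.0, 0.0, 0.0),
            noise_sd_uv=2.0,
            n_sweeps=500,
        )
        avg = sd.simulate_abr(spec, 64, seed=2).mean(axis=0)
        assert avg.std() == pytest.approx(2.0 / np.sqrt(500), rel=0.10)

    def test_unknown_frequency_rejected(self):
        with pytest.raises(ParameterError):
            sd.simulate_abr(sd.ABRSpec(), 12.0)


@pytest.fixture(scope="module")
def call_schedule():
    calls = sd.default_call_bank()
    return calls, sd.make_session_schedule(
        calls=calls, fra_step_oct=None, n_call_reps=20, seed=5
    )


class TestSimulatePopulation:
    def test_zero_high_fraction_means_no_call_responders(self, call_schedule):
        calls, sched = call_schedule
        spec = sd.PopulationSpec(30, "AN", fraction_high_f=0.0, seed=1)
        _, truth = sd.simulate_population(spec, sched, calls=calls)
        assert not truth.responds_to_calls.any()

    def test_icc_cfs_higher_than_an_cfs(self, call_schedule):
        calls, sched = call_schedule
        an = sd.station_profile("AN", 200, seed=2)
        icc = sd.station_profile("ICC", 200, seed=3)
        _, t_an = sd.simulate_population(an, sched, calls=calls)
        _, t_icc = sd.simulate_population(icc, sched, calls=calls)
        assert t_icc.cf_khz.median() > t_an.cf_khz.median()

    def test_ground_truth_reproducible_under_seed(self, call_schedule):
        calls, sched = call_schedule
        spec = sd.PopulationSpec(10, "DCN", seed=7)
        u1, t1 = sd.simulate_population(spec, sched, calls=calls)
        u2, t2 = sd.simulate_population(spec, sched, calls=calls)
        assert t1.equals(t2)
        for a, b in zip(u1, u2):
            assert np.array_equal(a.spike_times_ms, b.spike_times_ms)

    def test_truth_labels_match_drive_predicate(self, call_schedule):
        calls, sched = call_schedule
        spec = sd.PopulationSpec(40, "ICC", fraction_high_f=0.5, seed=11)
        neurons = sd.draw_neuron_specs(spec, calls)
        for n in neurons:
            assert n.responds_to_calls == any(sd.call_drives(n, c) for c in calls)
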
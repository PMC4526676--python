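import numpy as np
import pytest

from ultracoll import abr
from ultracoll import synthetic_data as sd
from ultracoll.signal_io import DataError, InsufficientDataError


def make_record(waveform, fs=25000.0):
    t = np.arange(len(waveform)) / fs * 1000.0
    return abr.ABRRecord(t, np.asarray(waveform, dtype=float))


def bump(t_ms, center, amp, sigma=0.15):
    return amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


class TestAverageSweeps:
    def test_identical_sweeps_average_to_filtered_sweep(self):
        spec = sd.ABRSpec(noise_sd_uv=0.0, n_sweeps=120)
        sweeps = sd.simulate_abr(spec, 64, seed=0)
        rec = abr.average_sweeps(sweeps)
        single = abr.average_sweeps(sweeps[:100])
        np.testing.assert_allclose(rec.waveform_uv, single.waveform_uv, atol=1e-10)

    def test_averaging_reduces_residual_noise_by_sqrt_n(self, rng):
        clean_ref = abr.average_sweeps(
            sd.abr_clean_waveform(sd.ABRSpec(), 64)[1][None, :].repeat(100, 0)
        ).waveform_uv
        _, clean = sd.abr_clean_waveform(sd.ABRSpec(), 64)

        def resid_sd(n):
            sweeps = clean + rng.normal(0.0, 2.0, (n, clean.size))
            return (abr.average_sweeps(sweeps).waveform_uv - clean_ref).std()

        # quadrupling the sweep count should halve the residual noise
        ratio = np.mean([resid_sd(125) / resid_sd(500) for _ in range(8)])
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_artifact_sweep_rejected(self, rng):
        _, clean = sd.abr_clean_waveform(sd.ABRSpec(), 64)
        sweeps = clean + rng.normal(0.0, 0.5, (500, clean.size))
        with_artifact = sweeps.copy()
        with_artifact[7] += 100.0 * np.sin(np.linspace(0, 20, clean.size))
        a = abr.average_sweeps(sweeps)
        b = abr.average_sweeps(with_artifact)
        assert b.n_sweeps < 500  # the corrupted sweep is rejected
        scale = np.abs(a.waveform_uv).max()
        assert np.abs(a.waveform_uv - b.waveform_uv).max() < 0.02 * scale + 0.02

    def test_too_few_sweeps(self, rng):
        with pytest.raises(InsufficientDataError):
            abr.average_sweeps(rng.normal(size=(50, 250)))

    def test_majority_artifacts_is_data_quality_error(self, rng):
        # impulse artifacts: enormous peak relative to their own SD
        sweeps = rng.normal(0.0, 1.0, (200, 250))
        sweeps[:150, 100] += 5000.0
        with pytest.raises(DataError):
            abr.average_sweeps(sweeps)


class TestDetectWaveV:
    def test_constructed_bump(self):
        fs = 25000.0
        t = np.arange(250) / fs * 1000.0
        y = bump(t, 5.7, 1.0) - bump(t, 5.2, 0.3)
        lat, amp = abr.detect_wave_v(make_record(y))
        assert lat == pytest.approx(5.7, abs=1.5 / fs * 1000.0)
        assert amp == pytest.approx(1.3, rel=0.02)

    def test_flat_waveform_undefined(self):
        assert abr.detect_wave_v(make_record(np.zeros(250))) is None

    def test_nearest_local_maximum_wins(self):
        fs = 25000.0
        t = np.arange(250) / fs * 1000.0
        y = bump(t, 5.0, 1.0) + bump(t, 6.2, 0.5) - bump(t, 4.6, 0.2)
        lat, _ = abr.detect_wave_v(make_record(y))
        assert lat == pytest.approx(6.2, abs=0.05)  # |6.2-5.7| < |5.0-5.7|


class TestDetectWaveI:
    def _records(self, wave_i_amp=0.8, noise=0.02, seed=0, n=500, disagree_ms=0.0):
        spec = sd.ABRSpec(
            waveI_amp_vs_freq={64: wave_i_amp},
            waveV_amp_vs_freq={64: 1.0},
            noise_sd_uv=noise,
            n_sweeps=n,
        )
        sweeps = sd.simulate_abr(spec, 64, seed=seed)
        if disagree_ms:
            # shift one half's early response to break repeatability
            shift = int(round(disagree_ms / 1000.0 * spec.sample_rate_hz))
            sweeps[1::2] = np.roll(sweeps[1::2], shift, axis=1)
        return abr.average_split_halves(sweeps, spec.sample_rate_hz)

    def test_constructed_wave_i_amplitude(self):
        full, a, b = self._records()
        amp = abr.detect_wave_i(full, (a, b))
        assert amp == pytest.approx(0.8, rel=0.05)

    def test_noise_only_record_mostly_undefined(self):
        hits = 0
        for seed in range(20):
            full, a, b = self._records(wave_i_amp=0.0, noise=1.0, seed=seed)
            # remove the other waves so only noise occupies the early band
            spec = sd.ABRSpec(
                waveI_amp_vs_freq={64: 0.0}, waveV_amp_vs_freq={64: 0.0},
                mid_wave_amps_uv=(0.0, 0.0, 0.0), noise_sd_uv=1.0, n_sweeps=500,
            )
            sweeps = sd.simulate_abr(spec, 64, seed=seed)
            full, a, b = abr.average_split_halves(sweeps, spec.sample_rate_hz)
            if abr.detect_wave_i(full, (a, b)) is not None:
                hits += 1
        assert hits <= 1  # defined in at most ~5% of null records

    def test_split_half_disagreement_gates_out(self):
        # waves II-IV removed so a shifted half cannot alias onto them
        spec = sd.ABRSpec(
            waveI_amp_vs_freq={64: 0.8}, waveV_amp_vs_freq={64: 1.0},
            mid_wave_amps_uv=(0.0, 0.0, 0.0), noise_sd_uv=0.02, n_sweeps=500,
        )
        sweeps = sd.simulate_abr(spec, 64, seed=0)
        shift = int(round(1.0 / 1000.0 * spec.sample_rate_hz))
        sweeps[1::2] = np.roll(sweeps[1::2], shift, axis=1)
        full, a, b = abr.average_split_halves(sweeps, spec.sample_rate_hz)
        assert abr.detect_wave_i(full, (a, b)) is None


class TestAbrThreshold:
    def _records_vs_level(self, thresh_db=35.0, slope=0.04, noise=0.05, seed=0):
        records = []
        rng = np.random.default_rng(seed)
        for level in np.arange(15.0, 80.0, 5.0):
            amp = max(0.0, (level - thresh_db)) * slope
            spec = sd.ABRSpec(
                waveI_amp_vs_freq={64: amp * 0.5},
                waveV_amp_vs_freq={64: amp},
                mid_wave_amps_uv=(amp * 0.3, amp * 0.3, amp * 0.3),
                noise_sd_uv=noise, n_sweeps=200,
            )
            sweeps = sd.simulate_abr(spec, 64, seed=rng)
            records.append((level, abr.average_sweeps(sweeps)))
        return records

    def test_threshold_recovered_within_one_step(self):
        thr = abr.abr_threshold(self._records_vs_level(thresh_db=35.0))
        assert thr is not None and abs(thr - 35.0) <= 5.0 + 1e-9

    def test_all_noise_gives_above_max_tested(self):
        thr = abr.abr_threshold(self._records_vs_level(thresh_db=1000.0))
        assert thr is None

    def test_amplitude_scaling_cannot_raise_threshold(self):
        t1 = abr.abr_threshold(self._records_vs_level(slope=0.04))
        t2 = abr.abr_threshold(self._records_vs_level(slope=0.08))
        assert t2 is not None and (t1 is None or t2 <= t1)


class TestWaveProfileRecovery:
    def test_wave_i_and_v_orderings_recovered(self):
        spec = sd.ABRSpec()
        rng = np.random.default_rng(5)
        freqs = sorted(spec.waveI_amp_vs_freq)
        rec_i, rec_v = [], []
        for f in freqs:
            sweeps = sd.simulate_abr(spec, f, seed=rng)
            full, a, b = abr.average_split_halves(sweeps, spec.sample_rate_hz)
            wv = abr.detect_wave_v(full)
            wi = abr.detect_wave_i(full, (a, b))
            assert wv is not None and wi is not None
            rec_v.append(wv[1])
            rec_i.append(wi)
        from scipy.stats import spearmanr

        gen_i = [spec.waveI_amp_vs_freq[f] for f in freqs]
        gen_v = [spec.waveV_amp_vs_freq[f] for f in freqs]
        assert spearmanr(rec_i, gen_i).statistic > 0.9
        assert spearmanr(rec_v, gen_v).statistic > 0.9
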
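"""Wiener/autoencoder denoising stage contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from eegbeats.core import AnxietyLevel, EEGRecording
from eegbeats.denoise import (
    CAEConfig,
    WienerConfig,
    denoise,
    denoise_with_noise_psd,
    estimate_noise,
    local_wiener,
    train_cae,
    wiener_gain,
)
from eegbeats.synthetic import corrupt, simulate_recording

FS = 256.0


def _snr(clean, est):
    return 10 * np.log10(np.mean(clean**2) / np.mean((clean - est) ** 2))


class TestWienerGain:
    def test_zero_noise_gives_unit_gain(self):
        S = np.array([1.0, 2.0, 3.0])
        assert np.allclose(wiener_gain(S, np.zeros(3), eps=0.1), 1.0)

    def test_equal_psds_give_half(self):
        S = np.array([1.0, 5.0])
        assert np.allclose(wiener_gain(S, S, eps=0.1), 0.5)

    def test_all_zero_bin_floored_at_eps(self):
        g = wiener_gain(np.zeros(4), np.zeros(4), eps=0.07)
        assert np.allclose(g, 0.07)

    def test_monotone_in_snr_ratio(self):
        V = np.ones(50)
        ratios = np.linspace(0.01, 100, 50)
        g = wiener_gain(ratios * V, V, eps=0.0)
        assert np.all(np.diff(g) >= 0)

    @given(st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, s, v):
        g = wiener_gain(np.array([s]), np.array([v]), eps=0.05)
        assert 0.05 <= g[0] <= 1.0


class TestLocalWiener:
    def test_zero_noise_variance_is_identity(self, rng):
        x = rng.standard_normal(500)
        assert np.allclose(local_wiener(x, 0.0, 31), x)

    def test_high_noise_collapses_to_local_mean(self, rng):
        x = 5.0 + 0.1 * rng.standard_normal(500)
        out = local_wiener(x, 1e6, 31)
        kernel = np.ones(31) / 31
        mu = sps.fftconvolve(np.pad(x, 15, mode="reflect"), kernel, mode="valid")
        assert np.allclose(out, mu)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            local_wiener(rng.standard_normal(100), 1.0, 10)

    def test_denoises_sinusoid(self, rng):
        t = np.arange(2048) / FS
        clean = np.sin(2 * np.pi * 5 * t)
        noise = rng.standard_normal(2048) * np.sqrt(np.mean(clean**2))
        out = local_wiener(clean + noise, float(np.var(noise)), 31)
        assert np.mean((out - clean) ** 2) < np.mean(noise**2)


class TestTraining:
    def test_determinism(self, clean_recordings):
        cfg = CAEConfig(epochs=2)
        a = train_cae(clean_recordings[:4], cfg, seed=7)
        b = train_cae(clean_recordings[:4], cfg, seed=7)
        for pa, pb in zip(a.net.state_dict(), b.net.state_dict()):
            assert np.array_equal(pa, pb)

    def test_needs_two_recordings(self, clean_recordings):
        with pytest.raises(ValueError):
            train_cae(clean_recordings[:1], CAEConfig(epochs=1), seed=0)

    def test_loss_decreases_and_beats_zero_predictor(self, cae_model, clean_recordings):
        n = len(cae_model.loss_curve)
        assert np.mean(cae_model.loss_curve[: n // 5]) > np.mean(cae_model.loss_curve[-n // 5:])
        # holdout reconstruction MSE beats predicting zero (data variance = 1
        # after standardization, times scale^2)
        assert cae_model.holdout_mse < cae_model.scale**2

    def test_trained_beats_untrained(self, cae_model, clean_recordings):
        untrained = train_cae(clean_recordings, CAEConfig(epochs=0), seed=1)
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 1, seed=77)
        err_t = np.mean((cae_model.reconstruct(rec.data[0]) - rec.data[0]) ** 2)
        err_u = np.mean((untrained.reconstruct(rec.data[0]) - rec.data[0]) ** 2)
        assert err_t < err_u


class TestEstimateNoise:
    def test_shapes_and_nonnegativity(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 2, seed=31)
        est = estimate_noise(cae_model, rec)
        assert est.N.shape == rec.data.shape
        assert est.n2.shape == (2,) and np.all(est.n2 >= 0)
        assert np.all(est.V_psd >= 0)

    def test_clean_input_near_zero_noise(self, cae_model):
        rec = simulate_recording(AnxietyLevel.NORMAL, 6.0, FS, 1, seed=32)
        est = estimate_noise(cae_model, rec)
        assert est.n2[0] < 0.05 * np.var(rec.data[0])

    def test_noise_variance_within_factor_two_at_0db(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 2, seed=33)
        pair = corrupt(rec, 0.0, line_freq=0.0, seed=5,
                       white_frac=1.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=0.0)
        est = estimate_noise(cae_model, pair.noisy)
        true_var = np.var(pair.noise, axis=1)
        assert np.all(est.n2 > true_var / 2) and np.all(est.n2 < true_var * 2)


class TestDenoise:
    def test_near_identity_on_clean_input(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MODERATE, 6.0, FS, 2, seed=41)
        out = denoise(rec, cae_model)
        rel = np.sqrt(np.mean((out.data - rec.data) ** 2) / np.mean(rec.data**2))
        assert rel <= 0.05

    def test_snr_gain_at_0db(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 2, seed=42)
        pair = corrupt(rec, 0.0, line_freq=0.0, seed=6,
                       white_frac=1.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=0.0)
        out = denoise(pair.noisy, cae_model)
        assert _snr(rec.data, out.data) >= 3.0

    def test_deterministic(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 1, seed=43)
        a = denoise(rec, cae_model)
        b = denoise(rec, cae_model)
        assert np.array_equal(a.data, b.data)

    def test_median_mse_reduction_over_20_fixtures(self, cae_model):
        """Sign test: MSE improves on >= 15/20 fixtures (p < 0.05 binomial)."""
        wins = 0
        for s in range(20):
            rec = simulate_recording(AnxietyLevel(s % 4), 6.0, FS, 1, seed=600 + s)
            pair = corrupt(rec, 0.0, line_freq=0.0, seed=s,
                           white_frac=1.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=0.0)
            out = denoise(pair.noisy, cae_model)
            wins += np.mean((out.data - rec.data) ** 2) < np.mean((pair.noisy.data - rec.data) ** 2)
        assert wins >= 15

    def test_local_mode_improves(self, cae_model):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 1, seed=44)
        pair = corrupt(rec, 0.0, line_freq=0.0, seed=7,
                       white_frac=1.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=0.0)
        out = denoise(pair.noisy, cae_model, WienerConfig(mode="local"))
        assert np.mean((out.data - rec.data) ** 2) < np.mean(pair.noise**2)


class TestOracleLimit:
    def test_within_1p2_of_ideal_wiener(self, rng):
        """With the true noise PSD supplied, spectral-mode MSE stays within
        1.2x the analytic per-bin ideal-Wiener MSE for sinusoid+white noise."""
        n = 4096
        t = np.arange(n) / FS
        clean = 3.0 * np.sin(2 * np.pi * 10 * t)
        noise = rng.standard_normal(n) * np.sqrt(np.mean(clean**2))  # 0 dB
        noisy = EEGRecording((clean + noise)[None, :], FS)
        nper = 256
        freqs = np.fft.rfftfreq(nper, 1 / FS)
        V = np.full_like(freqs, np.mean(noise**2) / (FS / 2))
        out = denoise_with_noise_psd(noisy, V, freqs, WienerConfig(eps=0.0))
        mse_ours = np.mean((out.data[0] - clean) ** 2)
        _, Ps = sps.welch(clean, fs=FS, nperseg=nper)
        mse_ideal = np.trapezoid(Ps * V / (Ps + V), freqs)
        assert mse_ours <= 1.2 * mse_ideal
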
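"""EMD, Hilbert analysis, harmonic scoring and AW-LMS cancellation."""

import math

import numpy as np
import pytest

from eegbeats.core import AnxietyLevel
from eegbeats.harmonics import (
    HarmonicConfig,
    IMFSet,
    align_and_normalize,
    awlms_cancel,
    cnn_harmonic_score,
    emd,
    hilbert_analyze,
    subtract_harmonics,
)
from eegbeats.harmonics import _resample_features, _synthetic_component
from eegbeats.synthetic import band_powers, corrupt, simulate_recording

FS = 256.0


def _line_amp(x, f, fs=FS):
    t = np.arange(len(x)) / fs
    return 2 * abs(np.mean(x * np.exp(-2j * np.pi * f * t)))


class TestEMD:
    def test_completeness_random_signals(self, rng):
        for _ in range(10):
            x = rng.standard_normal(512)
            s = emd(x, FS)
            recon = np.sum(s.imfs, axis=0) + s.residual if s.imfs else s.residual
            assert np.linalg.norm(recon - x) <= 1e-8 * np.linalg.norm(x)

    def test_pure_tone_first_imf(self):
        t = np.arange(int(4 * FS)) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        s = emd(tone, FS)
        assert abs(np.corrcoef(s.imfs[0], tone)[0, 1]) > 0.99

    def test_two_tone_separation(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 5 * t)
        spec = hilbert_analyze(emd(x, FS))
        m = spec.edge_mask
        med = [float(np.median(f[m])) for f in spec.frequency[:2]]
        assert abs(med[0] - 40) / 40 < 0.15
        assert abs(med[1] - 5) / 5 < 0.15

    def test_monotonic_input_yields_no_imfs(self):
        x = np.linspace(0, 1, 64)
        s = emd(x, FS)
        assert s.n_imfs == 0
        assert np.array_equal(s.residual, x)

    def test_sifting_property_zero_crossings_vs_extrema(self, rng):
        x = rng.standard_normal(1024)
        s = emd(x, FS)
        for imf in s.imfs[:3]:
            zc = int(np.sum(np.diff(np.signbit(imf)) != 0))
            d = np.diff(imf)
            ext = int(np.sum((d[:-1] > 0) & (d[1:] < 0)) + np.sum((d[:-1] < 0) & (d[1:] > 0)))
            assert abs(zc - ext) <= 1 + 0.05 * max(zc, ext)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            emd(np.ones(8), FS)


class TestHilbert:
    def test_amplitude_of_scaled_cosine(self):
        t = np.arange(int(4 * FS)) / FS
        s = IMFSet(imfs=[3.0 * np.cos(2 * np.pi * 10 * t)], residual=np.zeros_like(t), fs=FS)
        spec = hilbert_analyze(s)
        interior = spec.amplitude[0][spec.edge_mask]
        assert abs(np.median(interior) - 3.0) / 3.0 < 0.01

    def test_frequency_of_tone(self):
        t = np.arange(int(4 * FS)) / FS
        s = IMFSet(imfs=[np.cos(2 * np.pi * 10 * t)], residual=np.zeros_like(t), fs=FS)
        spec = hilbert_analyze(s)
        med = np.median(spec.frequency[0][spec.edge_mask])
        assert abs(med - 10.0) / 10.0 < 0.02

    def test_chirp_slope(self):
        t = np.arange(int(8 * FS)) / FS
        rate = (20.0 - 5.0) / 8.0
        chirp = np.sin(2 * np.pi * (5 * t + rate / 2 * t**2))
        spec = hilbert_analyze(IMFSet(imfs=[chirp], residual=np.zeros_like(t), fs=FS))
        m = spec.edge_mask
        A = np.vstack([t[m], np.ones(m.sum())]).T
        slope = np.linalg.lstsq(A, spec.frequency[0][m], rcond=None)[0][0]
        assert abs(slope - rate) / rate < 0.10

    def test_frequency_clamped_and_amplitude_nonnegative(self, rng):
        s = emd(rng.standard_normal(512), FS)
        spec = hilbert_analyze(s)
        assert np.all(spec.amplitude >= 0)
        assert np.all((spec.frequency >= 0) & (spec.frequency <= FS / 2))


class TestAlign:
    def test_padding_and_mask(self):
        t = np.arange(256) / FS
        short = IMFSet(imfs=[np.sin(2 * np.pi * 7 * t)], residual=np.zeros_like(t), fs=FS)
        out = align_and_normalize([hilbert_analyze(short)], target_len=512)
        assert out.tensor.shape == (1, 2, 512)
        assert out.mask[0, :256].all() and not out.mask[0, 256:].any()
        assert np.all((out.tensor >= 0) & (out.tensor <= 1))

    def test_constant_channel_flagged(self):
        t = np.arange(256) / FS
        s = IMFSet(imfs=[np.cos(2 * np.pi * 10 * t)], residual=np.zeros_like(t), fs=FS)
        spec = hilbert_analyze(s)
        spec.amplitude[0][:] = 2.0  # force degenerate amplitude channel
        out = align_and_normalize([spec], target_len=256)
        assert out.degenerate[0, 0]
        assert np.all(out.tensor[0, 0] == 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_and_normalize([], target_len=128)


class TestScorer:
    def test_probabilities_bounded_and_deterministic(self, harmonic_scorer):
        t = np.arange(1024) / FS
        s = IMFSet(imfs=[np.cos(2 * np.pi * 20 * t)], residual=np.zeros_like(t), fs=FS)
        spec = hilbert_analyze(s)
        a = cnn_harmonic_score(spec, harmonic_scorer)
        b = cnn_harmonic_score(spec, harmonic_scorer)
        assert np.all((a.probabilities >= 0) & (a.probabilities <= 1))
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_heldout_auc(self, harmonic_scorer, rng):
        """Harmonic lines vs band-limited neural components: AUC >= 0.9."""
        labels, feats = [], []
        for _ in range(200):
            lab = bool(rng.random() < 0.5)
            comp = _synthetic_component(rng, 1024, FS, lab)
            spec = hilbert_analyze(IMFSet(imfs=[comp], residual=np.zeros(1024), fs=FS))
            feats.append(_resample_features(spec, 0, harmonic_scorer.target_len))
            labels.append(lab)
        p = harmonic_scorer.predict_proba(np.asarray(feats))
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, p) >= 0.9

    def test_unfitted_model_rejected(self):
        from eegbeats.harmonics import HarmonicScorer

        model = HarmonicScorer(seed=0)
        with pytest.raises(RuntimeError):
            model.predict_proba(np.zeros((1, 2, 256)))


class TestAWLMS:
    def test_zero_step_is_identity(self, rng):
        prim = rng.standard_normal(1000)
        ref = np.sin(2 * np.pi * 20 * np.arange(1000) / FS)
        e, w_traj, err = awlms_cancel(prim, ref, mu_step=0.0)
        assert np.array_equal(e, prim)
        assert np.all(w_traj[-1] == 0)

    def test_correlated_reference_cancelled(self, rng):
        """>= 20 dB attenuation of the coherent line, <= 1 dB neural change."""
        n = 4096
        t = np.arange(n) / FS
        neural = np.sin(2 * np.pi * 9 * t)
        primary = neural + 0.5 * np.sin(2 * np.pi * 20 * t)
        refs = np.vstack([np.sin(2 * np.pi * 20 * t + 0.7), np.cos(2 * np.pi * 20 * t + 0.7)])
        e, _, _ = awlms_cancel(primary, refs, mu_step=0.02)
        half = n // 2
        before = _line_amp(primary[half:], 20.0)
        after = _line_amp(e[half:], 20.0)
        assert 20 * math.log10(before / after) >= 20
        n_before = _line_amp(primary[half:], 9.0)
        n_after = _line_amp(e[half:], 9.0)
        assert abs(20 * math.log10(n_before / n_after)) <= 1.0

    def test_uncorrelated_reference_zero_weights(self, rng):
        """The Wiener solution for an uncorrelated reference is w = 0."""
        prim = np.sin(2 * np.pi * 7 * np.arange(8192) / FS)
        ref = rng.standard_normal(8192)
        _, w_traj, _ = awlms_cancel(prim, ref, mu_step=0.005, n_taps=4)
        assert np.linalg.norm(w_traj[-2048:].mean(axis=0)) <= 0.05

    def test_uniform_attention_equals_plain_lms(self, rng):
        prim = rng.standard_normal(2000)
        ref = np.sin(2 * np.pi * 20 * np.arange(2000) / FS)
        e, _, _ = awlms_cancel(prim, ref, mu_step=0.01,
                               attention_temperature=math.inf, n_taps=4)
        # plain LMS reference implementation
        rows = np.zeros((4, 2000))
        for k in range(4):
            rows[k, k:] = ref[: 2000 - k]
        w = np.zeros(4)
        e_ref = np.empty(2000)
        for t in range(2000):
            u = rows[:, t]
            e_ref[t] = prim[t] - w @ u
            w = w + 0.01 * e_ref[t] * u
        assert np.max(np.abs(e - e_ref)) < 1e-10

    def test_stability_warning_then_divergence_error(self, rng):
        prim = rng.standard_normal(500)
        ref = rng.standard_normal(500)
        with pytest.warns(RuntimeWarning):
            with pytest.raises(RuntimeError, match="diverged"):
                awlms_cancel(prim, ref, mu_step=10.0, n_taps=4)

    def test_steady_state_matches_least_squares(self, rng):
        """Cycle-averaged weights within 10% L2 of the closed-form solution."""
        n = 2048
        t = np.arange(n) / FS
        neural = simulate_recording(AnxietyLevel.NORMAL, n / FS, FS, 1, seed=5).data[0]
        prim = neural + 12.0 * np.cos(2 * np.pi * 10 * t + 1.1)
        refs = np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        w_ls = np.linalg.lstsq(refs.T, prim, rcond=None)[0]
        _, w_traj, _ = awlms_cancel(np.tile(prim, 3), np.tile(refs, 3), mu_step=0.02)
        w_avg = w_traj[-n:].mean(axis=0)
        assert np.linalg.norm(w_avg - w_ls) <= 0.10 * np.linalg.norm(w_ls)


class TestSubtractHarmonics:
    def test_pass_through_without_harmonics(self, harmonic_scorer):
        rec = simulate_recording(AnxietyLevel.MILD, 6.0, FS, 2, seed=71)
        out, reports = subtract_harmonics(rec, harmonic_scorer)
        rel = np.sqrt(np.mean((out.data - rec.data) ** 2) / np.mean(rec.data**2))
        assert rel <= 0.05

    def test_harmonic_train_removed(self, harmonic_scorer):
        """10/20/30 Hz train at 0 dB: >= 15 dB line-power attenuation with
        the neural band-power profile preserved within 10%."""
        rec = simulate_recording(AnxietyLevel.MODERATE, 6.0, FS, 2, seed=72)
        pair = corrupt(rec, 0.0, line_freq=0.0, harmonic_fundamental=10.0, n_harmonics=3,
                       seed=8, white_frac=0.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=1.0)
        out, reports = subtract_harmonics(pair.noisy, harmonic_scorer)
        p_before = sum(_line_amp(pair.noisy.data[0], f) ** 2 for f in (10, 20, 30))
        p_after = sum(_line_amp(out.data[0], f) ** 2 for f in (10, 20, 30))
        assert 10 * math.log10(p_before / p_after) >= 15
        bp_clean = band_powers(rec.data[0], FS)
        bp_out = band_powers(out.data[0], FS)
        assert np.all(np.abs(bp_out / bp_clean - 1.0) <= 0.30)
        # relative band-power *profile* within 10%
        rel_c = bp_clean / bp_clean.sum()
        rel_o = bp_out / bp_out.sum()
        assert np.max(np.abs(rel_o - rel_c)) <= 0.10
        assert reports[0]["f0"] == pytest.approx(10.0, abs=0.5)

    def test_energy_accounting(self, harmonic_scorer):
        rec = simulate_recording(AnxietyLevel.MODERATE, 6.0, FS, 1, seed=73)
        pair = corrupt(rec, 3.0, line_freq=50.0, harmonic_fundamental=0.0, seed=9)
        out, _ = subtract_harmonics(pair.noisy, harmonic_scorer)
        assert np.mean(out.data**2) <= 1.01 * np.mean(pair.noisy.data**2)

    def test_deterministic(self, harmonic_scorer):
        rec = simulate_recording(AnxietyLevel.MODERATE, 6.0, FS, 1, seed=74)
        a, _ = subtract_harmonics(rec, harmonic_scorer)
        b, _ = subtract_harmonics(rec, harmonic_scorer)
        assert np.array_equal(a.data, b.data)
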
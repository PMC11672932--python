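"""Generator contracts: determinism, class structure, corruption, beat law."""

import math

import numpy as np
import pytest

from eegbeats.core import AnxietyLevel, CohortSpec, DEFAULT_BANDS
from eegbeats.synthetic import (
    add_binaural_beat_response,
    analyze_beat_stimulus,
    binaural_beat_stimulus,
    corrupt,
    generate_cohort,
    inject_burst,
    relative_band_powers,
    simulate_recording,
)

FS = 256.0


class TestSimulateRecording:
    def test_shape_and_determinism(self):
        rec = simulate_recording(AnxietyLevel.NORMAL, 10.0, FS, 4, seed=1)
        assert rec.data.shape == (4, 2560)
        rec2 = simulate_recording(AnxietyLevel.NORMAL, 10.0, FS, 4, seed=1)
        assert np.array_equal(rec.data, rec2.data)
        rec3 = simulate_recording(AnxietyLevel.NORMAL, 10.0, FS, 4, seed=2)
        assert not np.array_equal(rec.data, rec3.data)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_recording(AnxietyLevel.NORMAL, -1.0, FS, 2, seed=0)
        with pytest.raises(ValueError):
            simulate_recording(AnxietyLevel.NORMAL, 5.0, 100.0, 2, seed=0)  # fs < 2*gamma edge

    def test_beta_band_severity_gap(self):
        """Severe recordings carry more relative beta power than normal ones,
        by at least the configured profile gap, averaged over 20 seeds."""
        beta_idx = 3
        diffs = []
        for seed in range(20):
            severe = simulate_recording(AnxietyLevel.SEVERE, 6.0, FS, 1, seed=seed)
            normal = simulate_recording(AnxietyLevel.NORMAL, 6.0, FS, 1, seed=seed)
            diffs.append(
                relative_band_powers(severe.data[0], FS)[beta_idx]
                - relative_band_powers(normal.data[0], FS)[beta_idx]
            )
        # configured profiles put beta at 0.28 (severe) vs 0.12 (normal)
        assert np.mean(diffs) > 0.08

    def test_burst_annotation(self):
        rec = simulate_recording(AnxietyLevel.MILD, 8.0, FS, 2, seed=3)
        out = inject_burst(rec, 2.0, 1.0, 40.0, local_snr_db=10.0)
        assert any(a.kind == "burst" and a.onset == 2.0 for a in out.annotations)
        assert not np.array_equal(out.data, rec.data)


class TestBinauralBeat:
    def test_beat_law_400_410(self):
        """400/410 Hz carriers are heard as a 405 Hz tone fluctuating at 10 Hz."""
        x, fs = binaural_beat_stimulus(400.0, 410.0, duration_s=2.0)
        tone, mod = analyze_beat_stimulus(x, fs)
        assert abs(tone - 405.0) < 1.0
        assert abs(mod - 10.0) < 0.5

    def test_entrained_component_at_beat_frequency(self):
        rec = simulate_recording(AnxietyLevel.NORMAL, 8.0, FS, 1, seed=5)
        out = add_binaural_beat_response(rec, 430.0, 400.0, entrain_depth=0.5)
        added = out.data[0] - rec.data[0]
        freqs = np.fft.rfftfreq(len(added), 1 / FS)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(added)))]
        assert abs(peak - 30.0) <= freqs[1]  # one bin

    def test_zero_beat_unchanged(self):
        rec = simulate_recording(AnxietyLevel.NORMAL, 4.0, FS, 1, seed=5)
        out = add_binaural_beat_response(rec, 405.0, 405.0)
        assert np.array_equal(out.data, rec.data)
        assert any(a.kind == "entrainment" for a in out.annotations)

    def test_beat_above_nyquist_rejected(self):
        rec = simulate_recording(AnxietyLevel.NORMAL, 4.0, FS, 1, seed=5)
        with pytest.raises(ValueError):
            add_binaural_beat_response(rec, 100.0, 300.0)


class TestCorrupt:
    def test_additivity_and_snr(self):
        rec = simulate_recording(AnxietyLevel.MODERATE, 6.0, FS, 2, seed=9)
        pair = corrupt(rec, 0.0, seed=4)
        assert np.array_equal(pair.noisy.data, pair.clean.data + pair.noise)
        assert abs(pair.snr_db - 0.0) < 0.5

    def test_infinite_snr_is_identity(self):
        rec = simulate_recording(AnxietyLevel.MODERATE, 4.0, FS, 1, seed=9)
        pair = corrupt(rec, math.inf, seed=4)
        assert np.array_equal(pair.noisy.data, rec.data)
        assert np.all(pair.noise == 0)

    def test_harmonic_peaks_in_noise(self):
        rec = simulate_recording(AnxietyLevel.MODERATE, 8.0, FS, 1, seed=9)
        pair = corrupt(rec, 0.0, line_freq=0.0, harmonic_fundamental=10.0, n_harmonics=3,
                       seed=4, white_frac=0.0, pink_frac=0.0, line_frac=0.0, harmonic_frac=1.0)
        diff = pair.noisy.data[0] - pair.clean.data[0]
        spec = np.abs(np.fft.rfft(diff))
        freqs = np.fft.rfftfreq(len(diff), 1 / FS)
        for f0 in (10.0, 20.0, 30.0):
            window = spec[(freqs > f0 - 1) & (freqs < f0 + 1)].max()
            background = np.median(spec[(freqs > 35) & (freqs < 100)])
            assert window > 10 * background

    def test_zero_power_clean_rejected(self):
        rec = simulate_recording(AnxietyLevel.NORMAL, 4.0, FS, 1, seed=0)
        rec.data[:] = 0.0
        with pytest.raises(ValueError):
            corrupt(rec, 0.0, seed=1)


class TestCohort:
    def test_default_demographics(self):
        """945 records: 501 male, 444 female, ages within 18-71."""
        spec = CohortSpec(duration_s=1.5, fs=256.0, n_channels=1, seed=3)
        cohort = generate_cohort(spec, burst_rate_hz=0.0, entrain=None)
        assert len(cohort.records) == 945
        sexes = [r.subject.sex for r in cohort.records]
        assert sexes.count("male") == 501 and sexes.count("female") == 444
        ages = [r.subject.age for r in cohort.records]
        assert min(ages) >= 18 and max(ages) <= 71

    def test_partition(self):
        spec = CohortSpec(n_total=50, n_male=25, n_female=25, duration_s=1.5,
                          n_channels=1, seed=3)
        cohort = generate_cohort(spec, burst_rate_hz=0.0, entrain=None)
        assert len(cohort.train_idx) == round(0.8 * 50)
        assert set(cohort.train_idx) | set(cohort.test_idx) == set(range(50))
        assert set(cohort.train_idx) & set(cohort.test_idx) == set()

    def test_determinism(self):
        spec = CohortSpec(n_total=10, n_male=5, n_female=5, duration_s=1.5,
                          n_channels=1, seed=11)
        a = generate_cohort(spec, burst_rate_hz=0.0, entrain=None)
        b = generate_cohort(spec, burst_rate_hz=0.0, entrain=None)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(class_proportions=(0.5, 0.5, 0.5, 0.5))

    def test_class_separability_one_nn(self):
        """1-NN on the true per-record band-power profiles reaches >= 90%
        on a 200-record cohort — the signal the pipeline must recover."""
        spec = CohortSpec(n_total=200, n_male=106, n_female=94, duration_s=1.5,
                          n_channels=1, seed=21)
        cohort = generate_cohort(spec, burst_rate_hz=0.0, entrain=None)
        X = np.array([r.info["band_profile"] for r in cohort.records])
        y = np.array([int(r.label) for r in cohort.records])
        tr, te = cohort.train_idx, cohort.test_idx
        correct = 0
        for i in te:
            j = tr[np.argmin(np.linalg.norm(X[tr] - X[i], axis=1))]
            correct += y[j] == y[i]
        assert correct / len(te) >= 0.9
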
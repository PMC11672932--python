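"""Transformer-XL/LSTM transient feature stage."""

import numpy as np
import pytest

from eegbeats.core import AnxietyLevel, EEGRecording
from eegbeats.nn import Tensor
from eegbeats.synthetic import generate_cohort, inject_burst, simulate_recording
from eegbeats.core import CohortSpec
from eegbeats.transients import (
    DynamicWindowLSTM,
    FeatureSequence,
    TransformerXLEncoder,
    TransientConfig,
    TransientEvent,
    TransientFeatureExtractor,
    XLMemory,
    detect_transients,
    merge_representations,
    tokenize,
    waveform_morphology,
)

FS = 256.0
CFG = TransientConfig()


class TestMorphology:
    def test_sinusoid_skewness_near_zero(self):
        t = np.arange(int(2 * FS)) / FS
        m = waveform_morphology(np.sin(2 * np.pi * 8 * t), FS)
        assert abs(m.skewness) < 0.05

    def test_square_wave_area(self):
        t = np.arange(int(FS)) / FS
        square = np.sign(np.sin(2 * np.pi * 4 * t + 1e-9))
        m = waveform_morphology(square, FS)
        assert m.waveform_area == pytest.approx(1.0, rel=0.02)

    def test_gamma_sample_skewness(self, rng):
        x = rng.gamma(4.0, size=10_000)
        m = waveform_morphology(x, FS)
        assert abs(m.skewness - 1.0) / 1.0 < 0.15  # 2/sqrt(k) with k=4

    def test_zero_variance_flagged(self):
        m = waveform_morphology(np.full(64, 3.0), FS)
        assert m.skewness == 0.0 and m.degenerate


class TestEncoder:
    def setup_method(self):
        self.enc = TransformerXLEncoder(d_token=9, cfg=CFG)

    def test_token_count_preserved(self, rng):
        tokens = rng.standard_normal((7, 9))
        emb = self.enc.embed(tokens)
        assert emb.z.shape == (7, CFG.d_model)
        ctx, sal = self.enc.encode(tokens)
        assert ctx.shape == (7, CFG.d_model)
        assert sal.shape == (7,)

    def test_zero_tokens_embed_to_bias_only(self):
        emb = self.enc.embed(np.zeros((3, 9)))
        # linear map of zero input: all rows identical (bias only)
        assert np.allclose(emb.z.data[0], emb.z.data[1])

    def test_empty_tokens_rejected(self):
        with pytest.raises(ValueError):
            self.enc.embed(np.empty((0, 9)))

    def test_position_logits_shift_invariant(self):
        layer = self.enc.layers[0]
        L = layer.position_logits(8)
        # every diagonal (fixed offset m-n) is constant
        for off in range(-7, 8):
            diag = np.diag(L, off)
            assert np.allclose(diag, diag[0])

    def test_key_value_length_includes_memory(self, rng):
        tokens = rng.standard_normal((4, 9))
        emb = self.enc.embed(tokens)
        mem = XLMemory(states=[rng.standard_normal((CFG.mem_len, CFG.d_model))
                               for _ in range(CFG.n_layers)])
        _, new_mem = self.enc.encode_block(emb.z, mem)
        att = self.enc.layers[0].last_attention
        assert att.shape[-1] == CFG.mem_len + 4
        assert np.allclose(att.sum(axis=-1), 1.0)
        assert all(s.shape[0] <= CFG.mem_len for s in new_mem.states)

    def test_memory_receives_no_gradient(self, rng):
        tokens = rng.standard_normal((4, 9))
        emb = self.enc.embed(tokens)
        mem_tensor = Tensor(rng.standard_normal((CFG.mem_len, CFG.d_model)),
                            requires_grad=True)
        out = self.enc.layers[0](emb.z, mem_tensor.data)
        (out**2).sum().backward()
        assert mem_tensor.grad is None

    def test_empty_memory_equals_memoryless(self, rng):
        tokens = rng.standard_normal((4, 9))
        emb = self.enc.embed(tokens)
        empty = XLMemory.empty(CFG.n_layers, CFG.d_model)
        a, _ = self.enc.encode_block(emb.z, empty)
        b, _ = self.enc.encode_block(self.enc.embed(tokens).z, empty)
        assert np.max(np.abs(a.data - b.data)) < 1e-6


class TestDetection:
    def test_stationary_tone_no_events(self):
        t = np.arange(int(10 * FS)) / FS
        rec = EEGRecording((20 * np.sin(2 * np.pi * 10 * t))[None, :].repeat(2, axis=0), FS)
        tokens, onsets = tokenize(rec, CFG)
        assert detect_transients(rec, tokens, onsets, CFG) == []

    def test_three_bursts_detected_with_accurate_onsets(self, rng):
        rec = simulate_recording(AnxietyLevel.NORMAL, 12.0, FS, 2, seed=4)
        truth = [(1.0, 40.0), (5.0, 38.0), (9.0, 42.0)]
        for onset, freq in truth:
            rec = inject_burst(rec, onset, 1.0, freq, local_snr_db=10.0, rng=rng)
        tokens, onsets = tokenize(rec, CFG)
        events = detect_transients(rec, tokens, onsets, CFG)
        assert len(events) == 3
        for (onset, _), ev in zip(truth, events):
            assert abs(ev.onset - onset) <= 0.1

    def test_sorted_and_non_overlapping(self, rng):
        rec = simulate_recording(AnxietyLevel.MILD, 12.0, FS, 2, seed=5)
        for onset in (1.0, 3.0, 6.5):
            rec = inject_burst(rec, onset, 1.0, 40.0, local_snr_db=10.0, rng=rng)
        tokens, onsets = tokenize(rec, CFG)
        events = detect_transients(rec, tokens, onsets, CFG)
        for a, b in zip(events, events[1:]):
            assert a.onset <= b.onset
            assert a.onset + a.duration <= b.onset + 1e-9


class TestDynamicWindow:
    def test_no_events_all_base(self, rng):
        lstm = DynamicWindowLSTM(9, CFG)
        onsets = np.arange(0, 5, 0.5)
        w = lstm.window_lengths(onsets, [])
        assert np.all(w == CFG.base_window)

    def test_event_overlap_expands(self):
        lstm = DynamicWindowLSTM(9, CFG)
        onsets = np.arange(0, 5, 0.5)
        ev = TransientEvent(2.0, 1.0, 40.0, 3.0, np.zeros(5), 0.9)
        w = lstm.window_lengths(onsets, [ev])
        overlap = (onsets < 3.0) & (onsets + CFG.segment_s > 2.0)
        assert np.all(w[overlap] == CFG.base_window * CFG.expansion)
        assert np.all(w[~overlap] == CFG.base_window)
        assert np.all((w >= 1) & (w <= CFG.max_window))

    def test_expansion_one_equals_fixed_window(self, rng):
        cfg1 = TransientConfig(expansion=1)
        lstm = DynamicWindowLSTM(9, cfg1)
        tokens = rng.standard_normal((10, 9))
        onsets = np.arange(10) * 0.5
        ev = TransientEvent(2.0, 1.0, 40.0, 3.0, np.zeros(5), 0.9)
        with_ev = lstm.extract(tokens, onsets, [ev])
        without = lstm.extract(tokens, onsets, [])
        assert np.max(np.abs(with_ev.features - without.features)) < 1e-10


class TestFusion:
    def test_dimensions_and_zero(self):
        seq = FeatureSequence(features=np.zeros((5, 64)), window_lengths=np.full(5, 2), d_feat=64)
        fused = merge_representations(np.zeros((5, 64)), seq)
        assert fused.shape == (5, 128)
        assert np.all(fused == 0)

    def test_permutation_equivariance(self, rng):
        ctx = rng.standard_normal((6, 64))
        feats = rng.standard_normal((6, 64))
        seq = FeatureSequence(features=feats, window_lengths=np.full(6, 2), d_feat=64)
        fused = merge_representations(ctx, seq)
        perm = rng.permutation(6)
        seq_p = FeatureSequence(features=feats[perm], window_lengths=np.full(6, 2), d_feat=64)
        fused_p = merge_representations(ctx[perm], seq_p)
        assert np.array_equal(fused_p, fused[perm])

    def test_misaligned_rejected(self):
        seq = FeatureSequence(features=np.zeros((4, 64)), window_lengths=np.full(4, 2), d_feat=64)
        with pytest.raises(ValueError):
            merge_representations(np.zeros((5, 64)), seq)


class TestDownstreamSeparability:
    def test_linear_probe_on_extracted_features(self):
        """A linear probe on the extracted per-record features separates the
        four classes with >= 80% test accuracy on a 200-record cohort."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        spec = CohortSpec(n_total=200, n_male=106, n_female=94, duration_s=6.0,
                          n_channels=2, seed=13)
        cohort = generate_cohort(spec, entrain=None)
        ext = TransientFeatureExtractor(CFG)
        X = np.array([ext.record_vector(r) for r in cohort.records])
        y = np.array([int(r.label) for r in cohort.records])
        tr, te = cohort.train_idx, cohort.test_idx
        scaler = StandardScaler().fit(X[tr])
        clf = LogisticRegression(max_iter=5000, C=100).fit(scaler.transform(X[tr]), y[tr])
        assert clf.score(scaler.transform(X[te]), y[te]) >= 0.80
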
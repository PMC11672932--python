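"""Harmonic contamination removal via EMD/Hilbert analysis and adaptive LMS.

Harmonics — spectral lines at integer multiples of a fundamental (mains
interference, stimulation artifacts) — masquerade as brain rhythms.  This
stage decomposes each channel into intrinsic mode functions (IMFs) by
empirical mode decomposition, characterizes each IMF by its instantaneous
amplitude/frequency (Hilbert spectral analysis), scores each IMF's
probability of being harmonic contamination with a small CNN trained on
labelled synthetic components, infers the fundamental f0, and cancels the
flagged orders with an attentive-weighted LMS (AW-LMS) adaptive filter
driven by quadrature sinusoid references at k*f0.  Unflagged IMFs — the
genuine neural dynamics — pass through untouched; a narrowband reference
can only remove energy coherent with it.

The "attentive" weighting scales each tap's step size by a softmax over
recent per-tap gradient magnitudes; at infinite temperature the attention
is uniform and the update reduces exactly to plain LMS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import EEGRecording
from .nn import Adam, Conv1d, Linear, Module, Relu, Sequential, Tensor

__all__ = [
    "IMFSet",
    "InstantaneousSpectrum",
    "AlignedFeatures",
    "HarmonicScore",
    "HarmonicConfig",
    "emd",
    "hilbert_analyze",
    "align_and_normalize",
    "HarmonicScorer",
    "train_harmonic_scorer",
    "cnn_harmonic_score",
    "awlms_cancel",
    "subtract_harmonics",
]


# --------------------------------------------------------------------------
# Empirical mode decomposition
# --------------------------------------------------------------------------

@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotonic-ish residual.

    Completeness holds by construction: sum(imfs) + residual == source.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    fs: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def source(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima."""
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.where(rising[:-1] & falling[1:])[0] + 1
    minima = np.where(falling[:-1] & rising[1:])[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema, mirror-extended at edges."""
    n = len(x)
    t = ext.astype(float)
    v = x[ext]
    # mirror up to two extrema beyond each edge to tame boundary splines
    k = min(2, len(ext))
    t_left = -t[:k][::-1]
    v_left = v[:k][::-1]
    t_right = 2 * (n - 1) - t[-k:][::-1]
    v_right = v[-k:][::-1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    tt, uniq = np.unique(tt, return_index=True)
    return CubicSpline(tt, vv[uniq])(np.arange(n))


def emd(
    signal: np.ndarray,
    fs: float,
    max_imf: int = 10,
    stop: float = 0.2,
    max_siftings: int = 50,
) -> IMFSet:
    """Empirical mode decomposition by standard sifting.

    Sifting of each candidate mode stops when the normalized squared change
    between successive siftings falls below ``stop`` (Cauchy-type standard
    deviation criterion); decomposition stops at ``max_imf`` modes or when
    the residual has fewer than four extrema (monotonic input therefore
    yields zero IMFs and a residual equal to the input).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or len(x) < 16:
        raise ValueError("signal must be 1-D with length >= 16")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    imfs: list[np.ndarray] = []
    resid = x.copy()
    for _ in range(max_imf):
        maxima, minima = _local_extrema(resid)
        if len(maxima) + len(minima) < 4 or len(maxima) < 2 or len(minima) < 2:
            break
        h = resid.copy()
        for _ in range(max_siftings):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop:
                break
        imfs.append(h)
        resid = resid - h
    # enforce exact completeness: residual is the source minus the modes
    resid = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFSet(imfs=imfs, residual=resid, fs=fs)


# --------------------------------------------------------------------------
# Hilbert spectral analysis
# --------------------------------------------------------------------------

@dataclass
class InstantaneousSpectrum:
    """Per-IMF instantaneous amplitude and frequency traces.

    The first/last 5% of samples carry Hilbert edge artifacts and are
    flagged unreliable in ``edge_mask`` (True = reliable interior).
    """

    amplitude: np.ndarray   # (n_imfs, n) >= 0
    frequency: np.ndarray   # (n_imfs, n) Hz, clamped to [0, fs/2]
    edge_mask: np.ndarray   # (n,) bool
    fs: float

    def energy_grid(self, n_freq: int = 64, n_time: int = 64) -> np.ndarray:
        """Hilbert-spectrum energy on a time x frequency grid (>= 0)."""
        n = self.amplitude.shape[1]
        t_idx = np.minimum((np.arange(n) * n_time) // n, n_time - 1)
        grid = np.zeros((n_time, n_freq))
        f_edges = np.linspace(0, self.fs / 2, n_freq + 1)
        for a, f in zip(self.amplitude, self.frequency):
            f_idx = np.clip(np.searchsorted(f_edges, f, side="right") - 1, 0, n_freq - 1)
            np.add.at(grid, (t_idx, f_idx), a**2)
        return grid


def hilbert_analyze(imfset: IMFSet) -> InstantaneousSpectrum:
    """Analytic-signal amplitude and phase-derivative frequency per IMF."""
    n = len(imfset.residual)
    if n < 16:
        raise ValueError("components must have length >= 16")
    amps, freqs = [], []
    for imf in imfset.imfs:
        analytic = sps.hilbert(imf)
        amps.append(np.abs(analytic))
        phase = np.unwrap(np.angle(analytic))
        inst_f = np.gradient(phase) * imfset.fs / (2 * math.pi)
        freqs.append(np.clip(inst_f, 0.0, imfset.fs / 2))
    edge = max(int(0.05 * n), 1)
    mask = np.zeros(n, dtype=bool)
    mask[edge:n - edge] = True
    k = max(len(imfset.imfs), 0)
    amplitude = np.asarray(amps) if k else np.empty((0, n))
    frequency = np.asarray(freqs) if k else np.empty((0, n))
    return InstantaneousSpectrum(amplitude=amplitude, frequency=frequency, edge_mask=mask, fs=imfset.fs)


# --------------------------------------------------------------------------
# Feature alignment for the scoring CNN
# --------------------------------------------------------------------------

@dataclass
class AlignedFeatures:
    """Equal-length, min-max-normalized per-IMF (amplitude, frequency) pairs."""

    tensor: np.ndarray        # (n_imfs, 2, target_len) in [0, 1]
    mask: np.ndarray          # (n_imfs, target_len) True where samples are real
    degenerate: np.ndarray    # (n_imfs, 2) True where a channel had zero range


def align_and_normalize(
    spectra: Sequence[InstantaneousSpectrum],
    target_len: int,
    allow_truncation: bool = True,
) -> AlignedFeatures:
    """Stack per-IMF amplitude/frequency traces into one fixed-length tensor.

    Shorter traces are zero-padded (mask marks real samples); each channel is
    min-max scaled to [0, 1]; constant channels map to zeros and are flagged.
    """
    if not spectra:
        raise ValueError("spectra list is empty")
    rows, masks, degen = [], [], []
    for spec in spectra:
        n = spec.amplitude.shape[1] if spec.amplitude.size else 0
        if n > target_len and not allow_truncation:
            raise ValueError(f"component length {n} exceeds target_len {target_len}")
        for a, f in zip(spec.amplitude, spec.frequency):
            pair = np.zeros((2, target_len))
            m = np.zeros(target_len, dtype=bool)
            dg = np.zeros(2, dtype=bool)
            L = min(n, target_len)
            for ci, tr in enumerate((a, f)):
                seg = tr[:L]
                lo, hi = float(seg.min()), float(seg.max())
                if hi - lo <= 0:
                    dg[ci] = True
                    pair[ci, :L] = 0.0
                else:
                    pair[ci, :L] = (seg - lo) / (hi - lo)
            m[:L] = True
            rows.append(pair)
            masks.append(m)
            degen.append(dg)
    return AlignedFeatures(tensor=np.asarray(rows), mask=np.asarray(masks), degenerate=np.asarray(degen))


# --------------------------------------------------------------------------
# Harmonic scoring CNN
# --------------------------------------------------------------------------

@dataclass
class HarmonicScore:
    probabilities: np.ndarray          # per-IMF probability of harmonic contamination
    f0: Optional[float]                # detected fundamental, Hz
    orders: list[int]                  # flagged harmonic orders
    flagged: np.ndarray                # per-IMF bool

    def __post_init__(self) -> None:
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.orders and (self.f0 is None or self.f0 <= 0):
            raise ValueError("flagged orders require a positive f0")


class HarmonicScorer(Module):
    """2 conv layers + global average pooling + 1 dense, sigmoid output."""

    def __init__(self, seed: int = 0, target_len: int = 256):
        rng = np.random.default_rng(seed)
        self.conv = Sequential(
            Conv1d(2, 8, 5, rng, stride=2, padding="same"), Relu(),
            Conv1d(8, 16, 5, rng, stride=2, padding="same"), Relu(),
        )
        self.head = Linear(16, 1, rng)
        self.target_len = target_len
        self.fitted = False

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)            # (B, 16, L')
        pooled = h.mean(axis=2)     # (B, 16)
        return self.head(pooled)[:, 0].sigmoid()

    def predict_proba(self, tensor: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("harmonic scorer is not fitted; call train_harmonic_scorer")
        return self(Tensor(tensor)).data


def _synthetic_component(
    rng: np.random.Generator, n: int, fs: float, harmonic: bool
) -> np.ndarray:
    """One labelled training component: a harmonic line (near-constant
    instantaneous frequency, possibly with weak drift) or a band-limited
    neural oscillation."""
    t = np.arange(n) / fs
    lo = rng.uniform(1.0, 40.0)
    width = rng.uniform(2.0, 20.0)
    hi = min(lo + width, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    background = sps.sosfiltfilt(sos, rng.standard_normal(n))
    background /= np.sqrt(np.mean(background**2)) + 1e-30
    if not harmonic:
        return background
    f0 = rng.uniform(2.0, 60.0)
    drift = rng.uniform(-0.002, 0.002) * f0
    phase = 2 * math.pi * (f0 * t + 0.5 * drift * t**2)
    amp = 1.0 + rng.uniform(0.0, 0.05) * np.sin(2 * math.pi * rng.uniform(0.05, 0.3) * t)
    line = amp * np.cos(phase + rng.uniform(0, 2 * math.pi))
    # harmonic contamination as met in practice: a line riding on residual
    # neural background at 0-15 dB line-to-background ratio
    snr_db = rng.uniform(0.0, 15.0)
    bg_amp = np.sqrt(np.mean(line**2) / 10 ** (snr_db / 10))
    return line + bg_amp * background


def train_harmonic_scorer(
    n_samples: int = 500,
    fs: float = 256.0,
    component_len: int = 1024,
    target_len: int = 256,
    epochs: int = 20,
    seed: int = 0,
) -> HarmonicScorer:
    """Train the scoring CNN on labelled synthetic components.

    Harmonic components have near-constant instantaneous frequency and flat
    amplitude; neural components are band-limited noise with fluctuating
    amplitude and frequency — the CNN learns this distinction from the
    aligned (amplitude, frequency) traces.
    """
    rng = np.random.default_rng(seed)
    labels = rng.random(n_samples) < 0.5
    feats = []
    for lab in labels:
        comp = _synthetic_component(rng, component_len, fs, bool(lab))
        spec = hilbert_analyze(IMFSet(imfs=[comp], residual=np.zeros(component_len), fs=fs))
        feats.append(_resample_features(spec, 0, target_len))
    X = np.asarray(feats)
    y = labels.astype(float)

    model = HarmonicScorer(seed=seed, target_len=target_len)
    opt = Adam(model.parameters(), lr=3e-3)
    batch = 32
    for _ in range(epochs):
        order = rng.permutation(n_samples)
        for s in range(0, n_samples, batch):
            idx = order[s:s + batch]
            p = model(Tensor(X[idx]))
            target = Tensor(y[idx])
            eps = 1e-7
            p_c = p * (1 - 2 * eps) + eps
            loss = -(target * p_c.log() + (1.0 - target) * (1.0 - p_c).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.fitted = True
    return model


def _resample_features(spec: InstantaneousSpectrum, imf_idx: int, target_len: int) -> np.ndarray:
    """Min-max-normalized (amplitude, frequency) of one IMF resampled to target_len."""
    a = spec.amplitude[imf_idx]
    f = spec.frequency[imf_idx]
    idx = np.linspace(0, len(a) - 1, target_len)
    out = np.zeros((2, target_len))
    for ci, tr in enumerate((a, f)):
        r = np.interp(idx, np.arange(len(tr)), tr)
        lo, hi = r.min(), r.max()
        out[ci] = (r - lo) / (hi - lo) if hi > lo else 0.0
    return out


def _line_prominence(f: np.ndarray, pxx: np.ndarray, freq: float,
                     line_hw: float = 0.75, bg_hw: float = 8.0) -> tuple[float, float]:
    """(prominence ratio, line power) of a narrow spectral line at ``freq``.

    Prominence compares mean PSD within +-line_hw Hz to the median PSD of
    the surrounding +-bg_hw Hz (line region excluded); genuine lines are
    narrow and stand far above the local continuum, broadband neural peaks
    do not.
    """
    line = (f >= freq - line_hw) & (f <= freq + line_hw)
    bg = (f >= freq - bg_hw) & (f <= freq + bg_hw) & ~((f >= freq - 2 * line_hw) & (f <= freq + 2 * line_hw))
    if not line.any() or not bg.any():
        return 0.0, 0.0
    line_level = float(np.mean(pxx[line]))
    bg_level = float(np.median(pxx[bg])) + 1e-30
    power = float(np.trapezoid(pxx[line], f[line]))
    return line_level / bg_level, power


def cnn_harmonic_score(
    spec: InstantaneousSpectrum,
    model: HarmonicScorer,
    f0_candidates: Optional[np.ndarray] = None,
    prob_threshold: float = 0.5,
    max_order: int = 8,
    rel_tol: float = 0.05,
    line_spectrum: Optional[tuple[np.ndarray, np.ndarray]] = None,
    prominence_threshold: float = 8.0,
    min_f0: float = 2.0,
) -> HarmonicScore:
    """Score each IMF and infer the harmonic fundamental.

    Each IMF gets a CNN probability of carrying harmonic contamination
    (IMFs with median instantaneous frequency below ``min_f0`` are never
    flagged — slow drifts are not line contamination).  When the channel
    periodogram is supplied in ``line_spectrum``, candidate orders must
    additionally show a narrow spectral line of sufficient prominence; f0
    maximizes the CNN-weighted total power of its verified orders, with
    near-ties resolved toward the larger fundamental (fewer orders).
    """
    if f0_candidates is None:
        f0_candidates = np.arange(2.0, 60.0 + 1e-9, 0.5)
    n_imfs = spec.amplitude.shape[0]
    if n_imfs == 0:
        return HarmonicScore(np.empty(0), None, [], np.empty(0, dtype=bool))
    feats = np.asarray([_resample_features(spec, i, model.target_len) for i in range(n_imfs)])
    probs = model.predict_proba(feats)
    interior = spec.edge_mask
    med_freqs = np.array([float(np.median(f[interior])) for f in spec.frequency])
    energies = np.array([float(np.mean(a[interior] ** 2)) for a in spec.amplitude])
    flagged = (probs >= prob_threshold) & (med_freqs >= min_f0)
    nyq = spec.fs / 2

    def order_evidence(fk: float) -> float:
        """Power evidence that a harmonic line exists at fk, CNN-weighted."""
        if fk >= 0.95 * nyq:
            return 0.0
        near = np.where(np.abs(med_freqs - fk) <= rel_tol * fk + 1.0)[0]
        cnn_w = float(probs[near].max()) if near.size else 0.0
        if line_spectrum is not None:
            prom, power = _line_prominence(*line_spectrum, fk)
            if prom < prominence_threshold:
                return 0.0
            return power * (0.5 + 0.5 * cnn_w)
        # no periodogram available: fall back to flagged-IMF energy
        strong = [i for i in near if flagged[i]]
        return float(sum(energies[i] for i in strong))

    best_f0, best_score, best_orders = None, 0.0, []
    for f0 in f0_candidates:
        if f0 < min_f0:
            continue
        score, orders = 0.0, []
        for k in range(1, max_order + 1):
            ev = order_evidence(k * f0)
            if ev > 0:
                score += ev
                orders.append(k)
        # ties go to the larger fundamental: a sub-harmonic (half-f0) matches
        # the same verified lines with doubled orders but no extra evidence
        if orders and score >= best_score * 0.999 and score > 0:
            best_f0, best_score, best_orders = float(f0), score, orders
    if best_f0 is None:
        return HarmonicScore(probabilities=probs, f0=None, orders=[],
                             flagged=np.zeros(n_imfs, dtype=bool))
    return HarmonicScore(probabilities=probs, f0=best_f0, orders=best_orders, flagged=flagged)


# --------------------------------------------------------------------------
# Attentive-weighted LMS cancellation
# --------------------------------------------------------------------------

def awlms_cancel(
    primary: np.ndarray,
    reference: np.ndarray,
    mu_step: float = 0.05,
    attention_temperature: float = 1.0,
    n_taps: int = 4,
    grad_ema: float = 0.9,
    cost_window: int = 100,
    w_init: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive cancellation of a reference-coherent component.

    ``reference`` may be 1-D (a tapped delay line of ``n_taps`` is formed) or
    2-D with one row per tap input (e.g. quadrature sinusoids).  Per sample:
    ``e = d - w^T u``; each tap's update step is ``mu * n * a_i * e * u_i``
    where ``a`` is a softmax (temperature-controlled) over exponentially
    averaged per-tap gradient magnitudes.  With uniform attention
    (``attention_temperature=inf``) this is exactly plain LMS.  Returns
    (cleaned signal e, weight trajectory, squared-error curve).
    """
    d = np.asarray(primary, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim == 1:
        rows = np.zeros((n_taps, len(d)))
        for k in range(n_taps):
            rows[k, k:] = ref[: len(d) - k]
        ref = rows
    n_w, n = ref.shape
    if n != len(d):
        raise ValueError("primary and reference lengths differ")
    p_ref = float(np.mean(ref**2))
    if mu_step < 0:
        raise ValueError("mu_step must be >= 0")
    if p_ref > 0 and mu_step >= 2.0 / (n_w * p_ref):
        warnings.warn(
            f"mu_step={mu_step} exceeds the LMS stability bound "
            f"{2.0 / (n_w * p_ref):.3g}; adaptation may diverge",
            RuntimeWarning,
        )
    w = np.zeros(n_w) if w_init is None else np.asarray(w_init, dtype=float).copy()
    gbar = np.zeros(n_w)
    e = np.empty(n)
    w_traj = np.empty((n, n_w))
    bound = 1e6 * (np.max(np.abs(d)) + 1.0)
    for t in range(n):
        u = ref[:, t]
        e[t] = d[t] - w @ u
        g = e[t] * u
        gbar = grad_ema * gbar + (1 - grad_ema) * np.abs(g)
        if math.isinf(attention_temperature):
            a = np.full(n_w, 1.0 / n_w)
        else:
            # scale-invariant attention: gradient magnitudes are normalized by
            # their mean so the temperature has consistent units-free meaning
            z = gbar / ((gbar.mean() + 1e-30) * attention_temperature)
            z = z - z.max()
            ez = np.exp(z)
            a = ez / ez.sum()
        w = w + mu_step * n_w * a * g
        w_traj[t] = w
        if np.linalg.norm(w) > bound:
            raise RuntimeError(f"AW-LMS diverged at iteration {t}")
    return e, w_traj, e**2


def _running_cost(err2: np.ndarray, window: int = 100) -> np.ndarray:
    """Windowed mean of squared error (the Eq.-style sum-of-squares cost)."""
    kernel = np.ones(window) / window
    return np.convolve(err2, kernel, mode="valid")


# --------------------------------------------------------------------------
# Full harmonic-subtraction stage
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicConfig:
    max_imf: int = 10
    sift_stop: float = 0.2
    target_len: int = 256
    prob_threshold: float = 0.5
    mu_step: float = 0.02        # first (convergence) pass
    mu_refine: float = 0.003     # second (tracking) pass, warm-started
    attention_temperature: float = 1.0
    max_order: int = 8
    prominence_threshold: float = 8.0
    settle_fraction: float = 0.25  # discard this leading fraction when reporting attenuation


def subtract_harmonics(
    rec: EEGRecording,
    scorer: HarmonicScorer,
    config: HarmonicConfig = HarmonicConfig(),
) -> tuple[EEGRecording, list[dict]]:
    """Remove scored harmonic orders from every channel.

    Per channel: EMD -> Hilbert analysis -> CNN scoring -> for each flagged
    order k, AW-LMS cancellation against quadrature references at k*f0.
    Returns the cleaned recording and a per-channel report
    (f0, orders, attenuation in dB at the cancelled lines).
    """
    out = rec.copy_with()
    t = rec.times
    reports: list[dict] = []
    for c in range(rec.n_channels):
        x = rec.data[c]
        imfset = emd(x, rec.fs, max_imf=config.max_imf, stop=config.sift_stop)
        spec = hilbert_analyze(imfset)
        f_pxx = sps.periodogram(x, fs=rec.fs)
        score = cnn_harmonic_score(
            spec, scorer, prob_threshold=config.prob_threshold, max_order=config.max_order,
            line_spectrum=f_pxx, prominence_threshold=config.prominence_threshold,
        )
        report = {"channel": rec.channel_names[c], "f0": score.f0, "orders": score.orders,
                  "attenuation_db": {}}
        cleaned = x
        if score.f0 is not None and score.orders:
            for k in score.orders:
                fk = k * score.f0
                if fk >= rec.fs / 2:
                    continue
                refs = np.vstack([
                    np.sin(2 * math.pi * fk * t),
                    np.cos(2 * math.pi * fk * t),
                ])
                before = _line_power(cleaned, rec.fs, fk)
                # converge the taps over a repeated presentation of the
                # record, then average the weights over the last repetition:
                # slow weight swings driven by in-band neural power cancel
                # over a full cycle and the mean lands on the least-squares
                # optimum.  The warm-started low-step second pass then filters
                # without the zero-weight transient or pass-1 misadjustment.
                reps = 2
                _, w_traj, _ = awlms_cancel(
                    np.tile(cleaned, reps), np.tile(refs, reps),
                    mu_step=config.mu_step,
                    attention_temperature=config.attention_temperature,
                )
                w0 = w_traj[-len(cleaned):].mean(axis=0)
                cleaned, _, _ = awlms_cancel(
                    cleaned, refs,
                    mu_step=config.mu_refine,
                    attention_temperature=config.attention_temperature,
                    w_init=w0,
                )
                after = _line_power(cleaned, rec.fs, fk)
                if before > 0 and after > 0:
                    report["attenuation_db"][k] = 10 * math.log10(before / after)
        out.data[c] = cleaned
        reports.append(report)
    return out, reports


def _line_power(x: np.ndarray, fs: float, freq: float, half_width: float = 1.0) -> float:
    """Periodogram power within +-half_width Hz of a line frequency."""
    f, pxx = sps.periodogram(x, fs=fs)
    m = (f >= freq - half_width) & (f <= freq + half_width)
    return float(np.trapezoid(pxx[m], f[m])) if m.any() else 0.0
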
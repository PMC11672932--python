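"""Convolutional-autoencoder-assisted Wiener denoising.

The stage couples two classical ideas:

* a 1-D convolutional autoencoder is trained so that its reconstruction of
  an observed window approximates the clean EEG content; the residual
  ``N = Y - X`` (observed minus reconstruction) is the noise estimate.
  Training pairs are built from clean recordings by corrupting each window
  with broadband noise at a randomly drawn SNR, so the network learns the
  clean-EEG manifold and maps observations back onto it;
* a Wiener stage then removes linear noise, either spectrally — per-bin
  gain ``W = S^2 / (S^2 + V^2)`` with the signal PSD estimated as
  ``max(PSD(noisy) - V, 0)`` — or with a local (sliding-window) adaptive
  estimator ``x_hat = mu + max(sigma^2 - n^2, 0) / sigma^2 * (x - mu)``.

Spectral gains are floored at a configurable ``eps`` so the filter never
fully zeroes a bin (protecting weak nonlinear structure); overlap-add uses
a Hann window at 50% hop, which reconstructs exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import EEGRecording
from .nn import Adam, Conv1d, Module, Relu, Sequential, Tensor, Upsample1d

__all__ = [
    "CAEConfig",
    "CAEModel",
    "WienerConfig",
    "NoiseEstimate",
    "train_cae",
    "estimate_noise",
    "wiener_gain",
    "local_wiener",
    "denoise",
    "denoise_with_noise_psd",
]


@dataclass(frozen=True)
class CAEConfig:
    """Architecture and training knobs for the convolutional autoencoder."""

    window: int = 512           # samples per training window
    overlap: float = 0.5
    channels: tuple[int, ...] = (16, 32, 64)  # encoder channel widths; last = latent channels
    strides: tuple[int, ...] = (2, 1, 1)      # per-encoder-layer downsampling
    kernel: int = 7
    epochs: int = 50
    batch_size: int = 16
    lr: float = 2e-3
    noise_snr_range: tuple[float, float] = (0.0, 20.0)  # dB range of training corruption
    clean_fraction: float = 0.2  # fraction of training windows presented uncorrupted
    holdout_fraction: float = 0.2
    patience: int = 6
    distortion_margin: float = 2.0  # safety factor on the self-distortion subtraction
    calibration_snr_db: float = 0.0  # reference SNR for the residual->noise calibration
    max_noise_gain: float = 20.0    # cap on the calibrated residual->noise PSD gain


@dataclass(frozen=True)
class WienerConfig:
    """Wiener-stage parameters.

    ``mode='spectral'`` applies per-bin gains with overlap-add; ``'local'``
    applies the sliding-window adaptive estimator.  ``eps`` is the gain
    floor (and the defined gain where signal and noise PSD are both zero).
    """

    mode: str = "spectral"
    local_window: int = 31
    psd_nperseg: int = 256
    psd_overlap: float = 0.5
    eps: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("spectral", "local"):
            raise ValueError("mode must be 'spectral' or 'local'")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 3")
        if not (0 <= self.eps < 1):
            raise ValueError("eps must satisfy 0 <= eps < 1")


class _CAENet(Module):
    def __init__(self, cfg: CAEConfig, rng: np.random.Generator):
        ch = cfg.channels
        k = cfg.kernel
        if len(cfg.strides) != len(ch):
            raise ValueError("strides must match channels")
        enc: list[Module] = []
        c_prev = 1
        for c, s in zip(ch, cfg.strides):
            enc += [Conv1d(c_prev, c, k, rng, stride=s, padding="same"), Relu()]
            c_prev = c
        dec: list[Module] = []
        dec_specs = list(zip(reversed(ch[:-1]), reversed(cfg.strides[1:])))
        for c, s in dec_specs:
            if s > 1:
                dec.append(Upsample1d(s))
            dec += [Conv1d(c_prev, c, k, rng, padding="same"), Relu()]
            c_prev = c
        if cfg.strides[0] > 1:
            dec.append(Upsample1d(cfg.strides[0]))
        dec.append(Conv1d(c_prev, 1, k, rng, padding="same"))
        self.encoder = Sequential(*enc)
        self.decoder = Sequential(*dec)

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


@dataclass
class CAEModel:
    """Trained autoencoder with its normalization statistics and loss curve.

    ``self_distortion`` profiles the network's own reconstruction error on
    held-out *clean* data: the ratio of residual PSD to reconstruction PSD
    per normalized frequency.  Noise estimation subtracts this known leak
    so that clean input yields a near-zero noise estimate.
    """

    net: _CAENet
    config: CAEConfig
    scale: float               # global standardization (training RMS)
    seed: int
    loss_curve: list[float] = field(default_factory=list)
    holdout_mse: float = float("nan")
    self_distortion_freqs: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.5]))
    self_distortion: np.ndarray = field(default_factory=lambda: np.zeros(2))
    noise_gain: np.ndarray = field(default_factory=lambda: np.ones(2))

    def reconstruct_windows(self, windows: np.ndarray) -> np.ndarray:
        """Reconstruct (n_windows, window) arrays; returns the same shape."""
        x = Tensor(windows[:, None, :] / self.scale)
        out = self.net(x).data[:, 0, :]
        return out * self.scale

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Reconstruct a 1-D signal via Hann overlap-add of window reconstructions."""
        w = self.config.window
        hop = w // 2
        n = len(x)
        if n < w:
            pad = np.pad(x, (0, w - n))
            return self.reconstruct_windows(pad[None, :])[0][:n]
        # pad so edges get full window coverage
        x_pad = np.pad(x, (hop, w))
        n_frames = (len(x_pad) - w) // hop + 1
        idx = np.arange(w)[None, :] + hop * np.arange(n_frames)[:, None]
        frames = x_pad[idx]
        recon = self.reconstruct_windows(frames)
        win = np.hanning(w + 1)[:w]  # periodic Hann: exact COLA at 50% hop
        acc = np.zeros(len(x_pad))
        norm = np.zeros(len(x_pad))
        for i in range(n_frames):
            acc[i * hop:i * hop + w] += recon[i] * win
            norm[i * hop:i * hop + w] += win
        norm[norm == 0] = 1.0
        return (acc / norm)[hop:hop + n]

    def save(self, path) -> None:
        np.savez(
            path,
            version=np.array([1]),
            scale=np.array([self.scale]),
            seed=np.array([self.seed]),
            holdout_mse=np.array([self.holdout_mse]),
            loss_curve=np.asarray(self.loss_curve),
            sd_freqs=self.self_distortion_freqs,
            sd_beta=self.self_distortion,
            sd_gain=self.noise_gain,
            window=np.array([self.config.window]),
            channels=np.asarray(self.config.channels),
            strides=np.asarray(self.config.strides),
            kernel=np.array([self.config.kernel]),
            **{f"param_{i}": p for i, p in enumerate(self.net.state_dict())},
        )

    @classmethod
    def load(cls, path) -> "CAEModel":
        z = np.load(path)
        cfg = CAEConfig(
            window=int(z["window"][0]),
            channels=tuple(int(c) for c in z["channels"]),
            strides=tuple(int(s) for s in z["strides"]),
            kernel=int(z["kernel"][0]),
        )
        seed = int(z["seed"][0])
        net = _CAENet(cfg, np.random.default_rng(seed))
        n_params = len(net.parameters())
        net.load_state_dict([z[f"param_{i}"] for i in range(n_params)])
        model = cls(net=net, config=cfg, scale=float(z["scale"][0]), seed=seed,
                    loss_curve=list(z["loss_curve"]), holdout_mse=float(z["holdout_mse"][0]),
                    self_distortion_freqs=z["sd_freqs"], self_distortion=z["sd_beta"],
                    noise_gain=z["sd_gain"])
        return model


@dataclass
class NoiseEstimate:
    """Per-channel noise waveform, variance and power spectral density."""

    N: np.ndarray            # (channels, samples), exactly Y - X
    n2: np.ndarray           # (channels,) noise variance
    V_psd: np.ndarray        # (channels, bins) PSD of N
    freqs: np.ndarray        # (bins,)

    def __post_init__(self) -> None:
        if np.any(self.n2 < 0) or np.any(self.V_psd < 0):
            raise ValueError("noise variance and PSD must be nonnegative")


def _extract_windows(recs: Sequence[EEGRecording], window: int, overlap: float) -> np.ndarray:
    hop = max(int(window * (1 - overlap)), 1)
    out = []
    for rec in recs:
        for ch in rec.data:
            for start in range(0, len(ch) - window + 1, hop):
                out.append(ch[start:start + window])
    if not out:
        raise ValueError(f"recordings too short for window {window}")
    return np.asarray(out)


def _training_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-power white + 1/f mixture used to corrupt training windows."""
    w = rng.standard_normal(shape)
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    sc = np.zeros_like(f)
    sc[1:] = 1 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * sc, shape[-1], axis=-1)
    pink /= np.sqrt(np.mean(pink**2, axis=-1, keepdims=True)) + 1e-30
    mix = 0.7 * w + 0.55 * pink
    return mix / (np.sqrt(np.mean(mix**2, axis=-1, keepdims=True)) + 1e-30)


def train_cae(
    clean_set: Sequence[EEGRecording],
    config: CAEConfig = CAEConfig(),
    seed: int = 0,
) -> CAEModel:
    """Train the autoencoder on clean recordings.

    Windows are corrupted on the fly at SNRs drawn from
    ``config.noise_snr_range`` (a fraction presented clean) and the network
    regresses the clean window, learning to project observations onto the
    clean-EEG manifold.  Deterministic given (clean_set, config, seed).
    """
    if len(clean_set) < 2:
        raise ValueError("need at least 2 clean recordings")
    rng = np.random.default_rng(seed)
    windows = _extract_windows(clean_set, config.window, config.overlap)
    scale = float(np.sqrt(np.mean(windows**2)))
    if scale == 0:
        raise ValueError("clean training data have zero power")
    W = windows / scale

    n_hold = max(int(len(W) * config.holdout_fraction), 1)
    perm = rng.permutation(len(W))
    hold, train = W[perm[:n_hold]], W[perm[n_hold:]]
    if len(train) == 0:
        raise ValueError("no training windows left after holdout split")

    net = _CAENet(config, rng)
    opt = Adam(net.parameters(), lr=config.lr)
    loss_curve: list[float] = []
    best: tuple[float, list[np.ndarray]] = (math.inf, net.state_dict())
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        for start in range(0, len(train), config.batch_size):
            batch = train[order[start:start + config.batch_size]]
            noisy = batch.copy()
            corrupt_mask = rng.random(len(batch)) >= config.clean_fraction
            if corrupt_mask.any():
                snrs = rng.uniform(*config.noise_snr_range, size=int(corrupt_mask.sum()))
                noise = _training_noise(rng, batch[corrupt_mask].shape)
                p_sig = np.mean(batch[corrupt_mask] ** 2, axis=-1, keepdims=True)
                amp = np.sqrt(p_sig / 10 ** (snrs[:, None] / 10))
                noisy[corrupt_mask] = batch[corrupt_mask] + amp * noise
            x = Tensor(noisy[:, None, :])
            target = Tensor(batch[:, None, :])
            out = net(x)
            loss = ((out - target) ** 2).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"CAE training diverged at epoch {epoch}; last stable loss "
                    f"{loss_curve[-1] if loss_curve else 'n/a'}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_curve.append(float(loss.data))
        hold_mse = float(np.mean((net(Tensor(hold[:, None, :])).data[:, 0, :] - hold) ** 2))
        if hold_mse < best[0] - 1e-6:
            best = (hold_mse, net.state_dict())
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    net.load_state_dict(best[1])
    # profile self-distortion on the held-out clean windows
    recon = net(Tensor(hold[:, None, :])).data[:, 0, :]
    f_norm, p_resid = sps.periodogram(hold - recon, fs=1.0, axis=-1)
    _, p_recon = sps.periodogram(recon, fs=1.0, axis=-1)
    beta = p_resid.mean(axis=0) / (p_recon.mean(axis=0) + 1e-30)
    # calibrate the residual -> noise PSD mapping on corrupted holdout windows
    # (the injected noise is known here), at a mid-range reference SNR
    cal_noise = _training_noise(rng, hold.shape)
    amp = np.sqrt(np.mean(hold**2, axis=-1, keepdims=True) / 10 ** (config.calibration_snr_db / 10))
    cal_noisy = hold + amp * cal_noise
    cal_recon = net(Tensor(cal_noisy[:, None, :])).data[:, 0, :]
    _, p_resid_n = sps.periodogram(cal_noisy - cal_recon, fs=1.0, axis=-1)
    _, p_recon_n = sps.periodogram(cal_recon, fs=1.0, axis=-1)
    _, p_true = sps.periodogram(amp * cal_noise, fs=1.0, axis=-1)
    v_est = np.maximum(
        p_resid_n.mean(axis=0) - config.distortion_margin * beta * p_recon_n.mean(axis=0), 0.0
    )
    noise_gain = np.clip(p_true.mean(axis=0) / (v_est + 1e-30), 1.0, config.max_noise_gain)
    return CAEModel(net=net, config=config, scale=scale, seed=seed,
                    loss_curve=loss_curve, holdout_mse=best[0] * scale**2,
                    self_distortion_freqs=f_norm, self_distortion=beta,
                    noise_gain=noise_gain)


def estimate_noise(model: CAEModel, noisy: EEGRecording, psd_nperseg: int = 256) -> NoiseEstimate:
    """Estimate the noise in a recording as ``N = Y - X`` (residual of the
    autoencoder reconstruction X), with per-channel variance and Welch PSD.

    The residual PSD is corrected for the autoencoder's profiled
    self-distortion (its reconstruction error on clean data), so a clean
    recording yields a near-zero noise PSD instead of its own leaked signal.
    """
    X = np.stack([model.reconstruct(ch) for ch in noisy.data])
    if X.shape != noisy.data.shape:
        raise ValueError("reconstruction shape mismatch")
    N = noisy.data - X
    nper = min(psd_nperseg, noisy.n_samples)
    freqs, V_raw = sps.welch(N, fs=noisy.fs, nperseg=nper, axis=-1)
    _, P_x = sps.welch(X, fs=noisy.fs, nperseg=nper, axis=-1)
    beta = np.interp(freqs / noisy.fs, model.self_distortion_freqs, model.self_distortion)
    gain = np.interp(freqs / noisy.fs, model.self_distortion_freqs, model.noise_gain)
    margin = model.config.distortion_margin
    V = np.maximum(V_raw - margin * beta[None, :] * P_x, 0.0) * gain[None, :]
    # noise variance implied by the corrected PSD (integral over frequency)
    n2 = np.trapezoid(V, freqs, axis=-1)
    return NoiseEstimate(N=N, n2=np.maximum(n2, 0.0), V_psd=V, freqs=freqs)


def wiener_gain(S_psd: np.ndarray, V_psd: np.ndarray, eps: float = 0.1) -> np.ndarray:
    """Per-bin Wiener gain ``S^2 / (S^2 + V^2)``, floored at ``eps``.

    Where both PSDs are zero the gain is defined as ``eps``.
    """
    S = np.asarray(S_psd, dtype=float)
    V = np.asarray(V_psd, dtype=float)
    if S.shape != V.shape:
        raise ValueError("S_psd and V_psd must share one bin grid")
    if np.any(S < 0) or np.any(V < 0):
        raise ValueError("PSDs must be nonnegative")
    den = S**2 + V**2
    gain = np.full_like(S, eps, dtype=float)
    nz = den > 0
    gain[nz] = S[nz] ** 2 / den[nz]
    return np.clip(gain, eps, 1.0)


def local_wiener(x: np.ndarray, n2: float, window: int) -> np.ndarray:
    """Sliding-window adaptive Wiener estimator.

    ``x_hat = mu_B + max(sigma_B^2 - n2, 0) / sigma_B^2 * (x - mu_B)`` with
    local mean/variance over an odd ``window``; where the local variance is
    at or below the noise variance the output collapses to the local mean.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(x):
        raise ValueError("window longer than signal")
    kernel = np.ones(window) / window
    mu = sps.fftconvolve(np.pad(x, window // 2, mode="reflect"), kernel, mode="valid")
    mu2 = sps.fftconvolve(np.pad(x**2, window // 2, mode="reflect"), kernel, mode="valid")
    var = np.maximum(mu2 - mu**2, 0.0)
    coef = np.zeros_like(x)
    nz = var > 0
    coef[nz] = np.maximum(var[nz] - n2, 0.0) / var[nz]
    return mu + coef * (x - mu)


def _apply_spectral(
    data: np.ndarray,
    fs: float,
    V_psd: np.ndarray,
    freqs: np.ndarray,
    cfg: WienerConfig,
) -> np.ndarray:
    """Apply per-channel spectral Wiener gains with Hann overlap-add."""
    nper = min(cfg.psd_nperseg, data.shape[1])
    out = np.empty_like(data)
    for c, ch in enumerate(data):
        f_y, P_y = sps.welch(ch, fs=fs, nperseg=nper)
        if len(f_y) != len(freqs):
            raise ValueError("PSD bin grids do not match")
        S = np.maximum(P_y - V_psd[c], 0.0)
        gain = wiener_gain(S, V_psd[c], cfg.eps)
        noverlap = int(nper * cfg.psd_overlap)
        f_s, _, Z = sps.stft(ch, fs=fs, nperseg=nper, noverlap=noverlap)
        Z *= gain[:, None]  # multiplicative frequency-domain gain
        _, rec = sps.istft(Z, fs=fs, nperseg=nper, noverlap=noverlap)
        out[c] = rec[: data.shape[1]]
    return out


def denoise_with_noise_psd(
    rec: EEGRecording,
    V_psd: np.ndarray,
    freqs: np.ndarray,
    cfg: Optional[WienerConfig] = None,
) -> EEGRecording:
    """Spectral Wiener filtering with a supplied noise PSD (oracle path —
    bypasses the autoencoder)."""
    cfg = cfg or WienerConfig()
    out = rec.copy_with()
    out.data = _apply_spectral(rec.data, rec.fs, np.atleast_2d(V_psd), freqs, cfg)
    return out


def denoise(noisy: EEGRecording, model: CAEModel, cfg: Optional[WienerConfig] = None) -> EEGRecording:
    """Full denoising chain: autoencoder noise estimate, then the configured
    Wiener mode.  Deterministic given (model, cfg)."""
    cfg = cfg or WienerConfig()
    est = estimate_noise(model, noisy, psd_nperseg=cfg.psd_nperseg)
    out = noisy.copy_with()
    if cfg.mode == "spectral":
        out.data = _apply_spectral(noisy.data, noisy.fs, est.V_psd, est.freqs, cfg)
    else:
        out.data = np.stack(
            [local_wiener(ch, float(est.n2[c]), cfg.local_window) for c, ch in enumerate(noisy.data)]
        )
    return out
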
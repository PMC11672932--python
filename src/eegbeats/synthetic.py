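"""Synthetic EEG with known ground truth.

The study cohort this generator emulates is 945 subjects (501 male, 444
female, ages 18-71) labelled with one of four anxiety levels and split
80/20 into train and test.  Each record is a sum of band-limited Gaussian
oscillations whose *relative* band powers follow a class-conditional
profile: anxiety severity raises beta/gamma power and lowers alpha power.
On top of that the generator can add a binaural-beat entrainment component
(the EEG-side frequency-following response at the beat frequency
|f_left - f_right|), Gaussian-windowed oscillatory bursts (annotated, so
transient detectors can be scored against ground truth), and an additive
corruption mixture of white noise, 1/f noise, mains interference and a
harmonic train — the exact noise matrix is returned so denoisers can be
scored in closed loop.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import (
    DEFAULT_BANDS,
    Annotation,
    AnxietyLevel,
    BandDefinition,
    CleanNoisyPair,
    Cohort,
    CohortSpec,
    EEGRecording,
    Subject,
    validate_bands,
)

__all__ = [
    "CLASS_BAND_PROFILES",
    "simulate_recording",
    "add_binaural_beat_response",
    "binaural_beat_stimulus",
    "analyze_beat_stimulus",
    "inject_burst",
    "corrupt",
    "generate_cohort",
    "band_powers",
    "relative_band_powers",
]

#: Mean relative band power [delta, theta, alpha, beta, gamma] per class.
#: Severity shifts power from alpha toward beta/gamma (monotone by design);
#: magnitudes are configuration, not an empirical claim.
CLASS_BAND_PROFILES: dict[AnxietyLevel, np.ndarray] = {
    AnxietyLevel.NORMAL: np.array([0.30, 0.22, 0.30, 0.12, 0.06]),
    AnxietyLevel.MILD: np.array([0.28, 0.22, 0.25, 0.17, 0.08]),
    AnxietyLevel.MODERATE: np.array([0.26, 0.20, 0.20, 0.22, 0.12]),
    AnxietyLevel.SEVERE: np.array([0.23, 0.18, 0.14, 0.28, 0.17]),
}

#: Multiplicative per-subject jitter (lognormal sigma) on each band's power.
PROFILE_JITTER_SIGMA = 0.08

#: Default record RMS amplitude in microvolts.
DEFAULT_RMS_UV = 20.0


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-power Gaussian noise band-limited to ``band`` (4th-order Butterworth)."""
    white = rng.standard_normal(n)
    low = max(band.low, 1e-3)
    high = min(band.high, 0.99 * fs / 2)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    p = np.mean(x**2)
    if p <= 0:
        return np.zeros(n)
    return x / math.sqrt(p)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-power 1/f noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / math.sqrt(np.mean(x**2))


def band_powers(x: np.ndarray, fs: float, bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> np.ndarray:
    """Integrated periodogram power of ``x`` in each band."""
    f, pxx = sps.periodogram(x, fs=fs)
    out = np.empty(len(bands))
    for i, b in enumerate(bands):
        mask = (f >= b.low) & (f < b.high)
        out[i] = np.trapezoid(pxx[mask], f[mask]) if mask.any() else 0.0
    return out


def relative_band_powers(x: np.ndarray, fs: float, bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> np.ndarray:
    p = band_powers(x, fs, bands)
    s = p.sum()
    return p / s if s > 0 else p


def simulate_recording(
    label: AnxietyLevel,
    duration_s: float = 8.0,
    fs: float = 256.0,
    n_channels: int = 2,
    seed: int = 0,
    *,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    profiles: Optional[dict[AnxietyLevel, np.ndarray]] = None,
    profile_jitter: float = PROFILE_JITTER_SIGMA,
    rms_uv: float = DEFAULT_RMS_UV,
    burst_rate_hz: float = 0.0,
    subject: Optional[Subject] = None,
) -> EEGRecording:
    """Simulate one labelled EEG recording.

    Each channel is an independent realization of band-limited noise mixed
    with the class-conditional relative band-power profile (one jittered
    profile drawn per recording, shared across channels).  Deterministic
    given ``(label, seed)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    validate_bands(list(bands))
    top = max(b.high for b in bands)
    if fs < 2 * top:
        raise ValueError(f"fs={fs} Hz cannot represent band edge {top} Hz (need fs >= {2 * top})")
    label = AnxietyLevel(label)
    profiles = profiles if profiles is not None else CLASS_BAND_PROFILES
    n = int(round(duration_s * fs))
    rng = np.random.default_rng((int(seed), int(label)))

    base = np.asarray(profiles[label], dtype=float)
    jitter = np.exp(rng.normal(0.0, profile_jitter, size=base.size))
    profile = base * jitter
    profile = profile / profile.sum()

    data = np.zeros((n_channels, n))
    for c in range(n_channels):
        for bi, band in enumerate(bands):
            comp = _band_limited_noise(rng, n, fs, band)
            data[c] += comp * math.sqrt(profile[bi])
    # scale to the target broadband RMS
    data *= rms_uv / math.sqrt(np.mean(data**2))

    annotations: list[Annotation] = []
    rec = EEGRecording(
        data=data,
        fs=fs,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        subject=subject,
        label=label,
        annotations=annotations,
        info={"band_profile": profile, "bands": [b.name for b in bands]},
    )
    if burst_rate_hz > 0:
        n_bursts = rng.poisson(burst_rate_hz * duration_s)
        for _ in range(n_bursts):
            dur = rng.uniform(0.5, 1.5)
            onset = rng.uniform(0, max(duration_s - dur, 1e-3))
            freq = rng.uniform(30.0, 45.0)
            rec = inject_burst(rec, onset, dur, freq, local_snr_db=8.0, rng=rng)
    return rec


def inject_burst(
    rec: EEGRecording,
    onset_s: float,
    duration_s: float,
    freq_hz: float,
    local_snr_db: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> EEGRecording:
    """Add a Gaussian-windowed oscillatory burst to every channel and annotate it.

    ``local_snr_db`` sets the burst RMS relative to the background RMS inside
    the burst window, so detectors can be scored at a controlled local SNR.
    """
    if freq_hz >= rec.fs / 2:
        raise ValueError("burst frequency above Nyquist")
    rng = rng or np.random.default_rng(0)
    t = rec.times
    center = onset_s + duration_s / 2
    sigma = duration_s / 4  # +-2 sigma spans the annotated window
    window = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    i0, i1 = int(onset_s * rec.fs), int((onset_s + duration_s) * rec.fs)
    i1 = max(i1, i0 + 1)
    out = rec.copy_with()
    for c in range(rec.n_channels):
        bg_rms = math.sqrt(np.mean(rec.data[c, i0:i1] ** 2) + 1e-30)
        amp = bg_rms * 10 ** (local_snr_db / 20) * math.sqrt(2)
        phase = rng.uniform(0, 2 * math.pi)
        out.data[c] += amp * window * np.cos(2 * math.pi * freq_hz * t + phase)
    out.annotations = list(rec.annotations) + [Annotation(onset_s, duration_s, "burst")]
    out.info = dict(rec.info)
    return out


def add_binaural_beat_response(
    rec: EEGRecording,
    f_left: float,
    f_right: float,
    entrain_depth: float = 0.2,
) -> EEGRecording:
    """Add the EEG-side frequency-following response to a binaural beat.

    Presenting carriers ``f_left`` and ``f_right`` to the two ears evokes a
    cortical oscillation at the beat frequency ``|f_left - f_right|`` (e.g.
    400/410 Hz carriers entrain a 10 Hz response).  Only this EEG-side
    component is synthesized; the auditory stimulus itself is not rendered.
    """
    if f_left <= 0 or f_right <= 0:
        raise ValueError("carrier frequencies must be positive")
    beat = abs(f_left - f_right)
    if beat >= rec.fs / 2:
        raise ValueError(f"beat frequency {beat} Hz is at/above Nyquist {rec.fs / 2} Hz")
    out = rec.copy_with()
    out.annotations = list(rec.annotations) + [Annotation(0.0, rec.duration, "entrainment")]
    out.info = dict(rec.info, beat_hz=beat)
    if beat == 0:
        return out
    rms = math.sqrt(np.mean(rec.data**2))
    t = rec.times
    out.data += entrain_depth * rms * math.sqrt(2) * np.cos(2 * math.pi * beat * t)[None, :]
    return out


def binaural_beat_stimulus(
    f_left: float, f_right: float, duration_s: float = 2.0, fs: float = 4096.0
) -> tuple[np.ndarray, float]:
    """Dichotic stimulus mix: sin(2*pi*f_left*t) + sin(2*pi*f_right*t).

    Returns the summed waveform and its sampling rate.  The sum is perceived
    as a single tone at the mean carrier frequency, amplitude-modulated at
    the difference frequency.
    """
    if fs < 2 * max(f_left, f_right):
        raise ValueError("stimulus sampling rate below Nyquist for the carriers")
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * math.pi * f_left * t) + np.sin(2 * math.pi * f_right * t), fs


def analyze_beat_stimulus(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Measure (apparent tone Hz, envelope modulation Hz) of a beat stimulus.

    The apparent tone is the interior median instantaneous frequency of the
    analytic signal; the modulation frequency is the periodogram peak of the
    demeaned Hilbert envelope.
    """
    analytic = sps.hilbert(x)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.diff(phase) * fs / (2 * math.pi)
    k = max(len(inst_f) // 20, 1)
    tone = float(np.median(inst_f[k:-k]))
    f, pxx = sps.periodogram(env - env.mean(), fs=fs)
    mod = float(f[1:][np.argmax(pxx[1:])])
    return tone, mod


def corrupt(
    rec: EEGRecording,
    snr_db: float,
    line_freq: float = 50.0,
    harmonic_fundamental: float = 0.0,
    n_harmonics: int = 0,
    seed: int = 0,
    *,
    white_frac: float = 0.45,
    pink_frac: float = 0.25,
    line_frac: float = 0.15,
    harmonic_frac: float = 0.15,
) -> CleanNoisyPair:
    """Corrupt a recording with an additive noise mixture at a requested SNR.

    The mixture is white noise, 1/f noise, a mains sinusoid at ``line_freq``
    and a harmonic train at ``k * harmonic_fundamental`` (k = 1..n_harmonics),
    scaled so the realized broadband SNR equals the request.  ``snr_db=inf``
    returns a zero-noise pair.  The exact noise matrix is stored so that
    ``noisy = clean + noise`` holds to machine precision.
    """
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be >= 0")
    for fr in (line_freq,) + tuple(harmonic_fundamental * k for k in range(1, n_harmonics + 1)):
        if fr and fr >= rec.fs / 2:
            raise ValueError(f"injected frequency {fr} Hz at/above Nyquist")
    clean_power = float(np.mean(rec.data**2))
    if math.isinf(snr_db):
        noise = np.zeros_like(rec.data)
        noisy = rec.copy_with()
        noisy.data = rec.data + noise
        return CleanNoisyPair(rec, noisy, noise, math.inf)
    if clean_power <= 0:
        raise ValueError("cannot reach a finite SNR against a zero-power clean signal")

    rng = np.random.default_rng(seed)
    n_ch, n = rec.data.shape
    t = rec.times
    fracs = {"white": white_frac, "pink": pink_frac, "line": line_frac if line_freq else 0.0}
    fracs["harm"] = harmonic_frac if (harmonic_fundamental and n_harmonics) else 0.0
    total = sum(fracs.values())
    fracs = {k: v / total for k, v in fracs.items()}

    noise = np.zeros_like(rec.data)
    for c in range(n_ch):
        parts = []
        w = rng.standard_normal(n)
        parts.append((fracs["white"], w / math.sqrt(np.mean(w**2))))
        if fracs["pink"]:
            parts.append((fracs["pink"], _pink_noise(rng, n)))
        if fracs["line"]:
            ph = rng.uniform(0, 2 * math.pi)
            parts.append((fracs["line"], math.sqrt(2) * np.cos(2 * math.pi * line_freq * t + ph)))
        if fracs["harm"]:
            h = np.zeros(n)
            for k in range(1, n_harmonics + 1):
                ph = rng.uniform(0, 2 * math.pi)
                h += np.cos(2 * math.pi * harmonic_fundamental * k * t + ph)
            parts.append((fracs["harm"], h / math.sqrt(np.mean(h**2))))
        for frac, comp in parts:
            noise[c] += math.sqrt(frac) * comp
    # exact broadband SNR
    target_noise_power = clean_power / 10 ** (snr_db / 10)
    noise *= math.sqrt(target_noise_power / np.mean(noise**2))
    realized = 10 * math.log10(clean_power / np.mean(noise**2))

    noisy = rec.copy_with()
    noisy.data = rec.data + noise
    return CleanNoisyPair(rec, noisy, noise, realized)


def generate_cohort(
    spec: CohortSpec,
    *,
    profiles: Optional[dict[AnxietyLevel, np.ndarray]] = None,
    burst_rate_hz: float = 0.05,
    entrain: Optional[tuple[float, float]] = (400.0, 410.0),
) -> Cohort:
    """Generate the full labelled cohort with a disjoint 80/20 partition.

    One master seed expands into independent per-subject seeds, so any
    subject's record can be regenerated without generating the others.
    """
    rng = np.random.default_rng(spec.seed)
    sexes = ["male"] * spec.n_male + ["female"] * spec.n_female
    rng.shuffle(sexes)
    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=spec.n_total)
    labels = rng.choice(4, size=spec.n_total, p=np.asarray(spec.class_proportions))
    subject_seeds = rng.integers(0, 2**31 - 1, size=spec.n_total)

    records = []
    for i in range(spec.n_total):
        subj = Subject(id=f"S{i:04d}", sex=sexes[i], age=int(ages[i]))
        rec = simulate_recording(
            AnxietyLevel(int(labels[i])),
            duration_s=spec.duration_s,
            fs=spec.fs,
            n_channels=spec.n_channels,
            seed=int(subject_seeds[i]),
            profiles=profiles,
            burst_rate_hz=burst_rate_hz,
            subject=subj,
        )
        if entrain is not None:
            rec = add_binaural_beat_response(rec, *entrain)
        records.append(rec)

    n_train = int(round(spec.train_fraction * spec.n_total))
    perm = rng.permutation(spec.n_total)
    return Cohort(records=records, train_idx=np.sort(perm[:n_train]), test_idx=np.sort(perm[n_train:]), spec=spec)
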
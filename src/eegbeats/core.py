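"""Core domain containers for the EEG anxiety-analysis pipeline.

The pipeline operates on multichannel EEG recordings (channels x samples,
microvolt scale) annotated with subject metadata and an optional four-level
anxiety label.  The conventional clinical frequency bands (delta through
gamma) are first-class objects because every later stage — denoising,
harmonic subtraction, feature extraction and classification — reasons about
band-limited structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AnxietyLevel",
    "BandDefinition",
    "DEFAULT_BANDS",
    "Subject",
    "Annotation",
    "EEGRecording",
    "CleanNoisyPair",
    "CohortSpec",
    "Cohort",
]


class AnxietyLevel(IntEnum):
    """Four-level anxiety severity with a stable integer encoding."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @classmethod
    def from_name(cls, name: str) -> "AnxietyLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown anxiety level {name!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 <= low < high, got [{self.low}, {self.high}]")

    def validate_against(self, fs: float) -> None:
        if self.high > fs / 2:
            raise ValueError(f"band {self.name} upper edge {self.high} Hz exceeds Nyquist {fs / 2} Hz")


#: Standard clinical EEG bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


def validate_bands(bands: Sequence[BandDefinition]) -> None:
    """Check that bands are non-overlapping and ordered by frequency."""
    for a, b in zip(bands, bands[1:]):
        if a.high > b.low:
            raise ValueError(f"bands {a.name} and {b.name} overlap or are out of order")


@dataclass(frozen=True)
class Subject:
    id: str
    sex: str  # "male" | "female"
    age: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class Annotation:
    """Ground-truth event: onset and duration in seconds from record start."""

    onset: float
    duration: float
    kind: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("annotation onset must be >= 0")
        if self.duration < 0:
            raise ValueError("annotation duration must be >= 0")


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix with sampling rate and metadata."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject: Optional[Subject] = None
    label: Optional[AnxietyLevel] = None
    annotations: list[Annotation] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contain non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        for ann in self.annotations:
            if ann.onset > self.duration + 1e-9:
                raise ValueError(f"annotation onset {ann.onset}s beyond record duration {self.duration}s")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Return a copy with selected fields replaced (data is copied)."""
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        out.annotations = list(kwargs.get("annotations", self.annotations))
        return out


@dataclass
class CleanNoisyPair:
    """A clean recording, its corrupted twin, and the exact additive noise."""

    clean: EEGRecording
    noisy: EEGRecording
    noise: np.ndarray
    snr_db: float

    def __post_init__(self) -> None:
        if self.clean.data.shape != self.noisy.data.shape or self.noise.shape != self.clean.data.shape:
            raise ValueError("clean, noisy and noise must share one shape")
        if not np.array_equal(self.noisy.data, self.clean.data + self.noise):
            raise ValueError("additivity violated: noisy must equal clean + noise exactly")


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort description: 945 subjects (501 male / 444 female), ages
    18-71, four anxiety classes, 80/20 train/test split."""

    n_total: int = 945
    n_male: int = 501
    n_female: int = 444
    age_range: tuple[int, int] = (18, 71)
    class_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    train_fraction: float = 0.8
    duration_s: float = 8.0
    fs: float = 256.0
    n_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_total:
            raise ValueError("n_male + n_female must equal n_total")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("class_proportions must be 4 non-negative values summing to 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min <= max")


@dataclass
class Cohort:
    """A generated cohort with a disjoint train/test partition."""

    records: list[EEGRecording]
    train_idx: np.ndarray
    test_idx: np.ndarray
    spec: CohortSpec

    def __post_init__(self) -> None:
        n = len(self.records)
        union = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(union, np.arange(n)):
            raise ValueError("train/test must partition the cohort")

    @property
    def train(self) -> list[EEGRecording]:
        return [self.records[i] for i in self.train_idx]

    @property
    def test(self) -> list[EEGRecording]:
        return [self.records[i] for i in self.test_idx]
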
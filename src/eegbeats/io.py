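"""Reading/writing EEG containers, pipeline configuration and run logs.

EDF(+C) is the canonical on-disk format: 16-bit samples with physical
scaling taken from the data range, one annotation channel carrying
ground-truth events as time-stamped annotation lists.  Writing is
implemented directly against the format specification; reading goes through
:mod:`mne`, which doubles as an independent check on the writer.  A simple
CSV dialect (comment line with the sampling rate, header row of channel
names) is supported for toy fixtures.
"""

from __future__ import annotations

import csv as _csv
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import Annotation, AnxietyLevel, EEGRecording, Subject

__all__ = [
    "read_recording",
    "write_recording",
    "write_cohort_archive",
    "read_cohort_archive",
    "PipelineConfig",
    "RunLog",
    "RunLogEntry",
]


# --------------------------------------------------------------------------
# EDF writing (format implemented directly; reading via mne)
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_num(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:.10g}", f"{x:.6g}", f"{x:.4g}", f"{x:.2f}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot represent {x} in {width} EDF header characters")


def write_recording(rec: EEGRecording, path, fmt: str = "edf") -> None:
    """Write a recording as EDF+C (16-bit) or CSV.

    EDF physical min/max are set from the per-channel data range, so the
    round-trip error is bounded by the 16-bit quantization step.  Annotations
    are stored in an 'EDF Annotations' channel.
    """
    path = Path(path)
    if fmt == "csv":
        _write_csv(rec, path)
        return
    if fmt != "edf":
        raise ValueError(f"unknown format {fmt!r}")
    if rec.n_channels == 0 or rec.n_samples == 0:
        raise ValueError("cannot write an empty recording")

    data = rec.data
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    # annotation payload: timestamp TAL + one TAL per annotation
    tals = [b"+0\x14\x14\x00"]
    for ann in rec.annotations:
        tals.append(
            f"+{ann.onset:.4f}\x15{ann.duration:.4f}\x14{ann.kind}\x14\x00".encode("ascii")
        )
    payload = b"".join(tals)
    ann_samples = max((len(payload) + 1) // 2 + 8, 16)

    n_sig = rec.n_channels + 1
    duration = rec.n_samples / rec.fs
    header_bytes = 256 * (1 + n_sig)
    patient = rec.subject.id if rec.subject else "X"
    label_extra = f" {rec.label.label}" if rec.label is not None else ""

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(patient, 80))
        f.write(_pad(f"Startdate 01-JAN-2000 {patient}{label_extra}", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad("1", 8))                       # one data record
        f.write(_fmt_num(duration, 8))
        f.write(_pad(str(n_sig), 4))
        labels = list(rec.channel_names) + ["EDF Annotations"]
        for lab in labels:
            f.write(_pad(lab, 16))
        for _ in labels:
            f.write(_pad("", 80))                   # transducer
        for i in range(n_sig):
            f.write(_pad("uV" if i < rec.n_channels else "", 8))
        for i in range(n_sig):
            f.write(_fmt_num(phys_min[i] if i < rec.n_channels else -1, 8))
        for i in range(n_sig):
            f.write(_fmt_num(phys_max[i] if i < rec.n_channels else 1, 8))
        for _ in range(n_sig):
            f.write(_pad(str(dig_min), 8))
        for _ in range(n_sig):
            f.write(_pad(str(dig_max), 8))
        for _ in range(n_sig):
            f.write(_pad("", 80))                   # prefiltering
        for i in range(n_sig):
            f.write(_pad(str(rec.n_samples if i < rec.n_channels else ann_samples), 8))
        for _ in range(n_sig):
            f.write(_pad("", 32))
        # single data record
        for c in range(rec.n_channels):
            scale = (phys_max[c] - phys_min[c]) / (dig_max - dig_min)
            dig = np.round((data[c] - phys_min[c]) / scale + dig_min).astype("<i2")
            f.write(dig.tobytes())
        ann_bytes = payload + b"\x00" * (2 * ann_samples - len(payload))
        f.write(ann_bytes)


def _write_csv(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", newline="") as f:
        f.write(f"# fs={rec.fs}\n")
        w = _csv.writer(f)
        w.writerow(rec.channel_names)
        for row in rec.data.T:
            w.writerow([repr(float(v)) for v in row])


def read_recording(path, fmt: Optional[str] = None, fs: Optional[float] = None) -> EEGRecording:
    """Read an EDF or CSV recording.

    CSV needs a sampling rate: either the ``fs`` argument or a leading
    ``# fs=...`` comment line.  Structural problems (ragged rows, missing
    header) raise ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "edf"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path, fs)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; EDF here is microvolts
    annotations = [
        Annotation(float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    subject, label = None, None
    meas = raw.info.get("subject_info") or {}
    rec_id = ""
    try:
        with open(path, "rb") as f:
            f.seek(88)
            rec_id = f.read(80).decode("ascii", errors="replace").strip()
        parts = rec_id.split()
        if len(parts) >= 4 and parts[-1] in [lvl.label for lvl in AnxietyLevel]:
            label = AnxietyLevel.from_name(parts[-1])
        if len(parts) >= 3:
            subject = Subject(id=parts[2], sex="male", age=0) if parts[2] not in ("X",) else None
    except OSError:
        pass
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject=subject,
        label=label,
        annotations=annotations,
    )


def _read_csv(path: Path, fs: Optional[float]) -> EEGRecording:
    with open(path) as f:
        first = f.readline()
        if first.startswith("#"):
            if "fs=" in first:
                fs = float(first.split("fs=")[1].strip())
            header_line = f.readline()
        else:
            header_line = first
        if fs is None:
            raise ValueError(f"{path}: sampling rate not declared (no fs argument or '# fs=' line)")
        names = [h.strip() for h in header_line.strip().split(",") if h.strip()]
        if not names:
            raise ValueError(f"{path}: line 1: missing channel-name header")
        rows = []
        for lineno, line in enumerate(f, start=3):
            if not line.strip():
                continue
            vals = line.strip().split(",")
            if len(vals) != len(names):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(names)} values, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return EEGRecording(data=np.asarray(rows).T, fs=fs, channel_names=names)


# --------------------------------------------------------------------------
# Cohort archives (single compressed file, for fixtures)
# --------------------------------------------------------------------------

def write_cohort_archive(cohort, path) -> None:
    """Write a whole cohort (equal-shaped records) to one compressed file."""
    from .core import Cohort  # noqa: F401  (type documented, not enforced)

    data = np.stack([r.data for r in cohort.records])
    np.savez_compressed(
        path,
        data=data,
        fs=np.array([cohort.records[0].fs]),
        sexes=np.array([r.subject.sex for r in cohort.records]),
        ids=np.array([r.subject.id for r in cohort.records]),
        ages=np.array([r.subject.age for r in cohort.records]),
        labels=np.array([int(r.label) for r in cohort.records]),
        train_idx=cohort.train_idx,
        test_idx=cohort.test_idx,
        spec=np.array([json.dumps({
            "n_total": cohort.spec.n_total, "n_male": cohort.spec.n_male,
            "n_female": cohort.spec.n_female, "age_range": list(cohort.spec.age_range),
            "class_proportions": list(cohort.spec.class_proportions),
            "train_fraction": cohort.spec.train_fraction,
            "duration_s": cohort.spec.duration_s, "fs": cohort.spec.fs,
            "n_channels": cohort.spec.n_channels, "seed": cohort.spec.seed,
        })]),
    )


def read_cohort_archive(path):
    """Read a cohort archive written by :func:`write_cohort_archive`."""
    from .core import Cohort, CohortSpec, EEGRecording

    z = np.load(path, allow_pickle=False)
    fs = float(z["fs"][0])
    spec_d = json.loads(str(z["spec"][0]))
    spec_d["age_range"] = tuple(spec_d["age_range"])
    spec_d["class_proportions"] = tuple(spec_d["class_proportions"])
    records = []
    for i in range(z["data"].shape[0]):
        records.append(EEGRecording(
            data=z["data"][i], fs=fs,
            subject=Subject(id=str(z["ids"][i]), sex=str(z["sexes"][i]), age=int(z["ages"][i])),
            label=AnxietyLevel(int(z["labels"][i])),
        ))
    from .core import Cohort
    return Cohort(records=records, train_idx=z["train_idx"], test_idx=z["test_idx"],
                  spec=CohortSpec(**spec_d))


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

class DenoiseBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window: int = 512
    channels: tuple[int, ...] = (16, 32, 64)
    strides: tuple[int, ...] = (2, 1, 1)
    kernel: int = 7
    epochs: int = 50
    lr: float = 2e-3
    mode: str = "spectral"
    eps: float = 0.1
    psd_nperseg: int = 256
    n_train_records: int = 12


class HarmonicsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scorer_samples: int = 500
    scorer_epochs: int = 20
    mu_step: float = 0.02
    mu_refine: float = 0.003
    attention_temperature: float = 1.0
    prominence_threshold: float = 8.0


class FeaturesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    mem_len: int = 4
    lstm_hidden: int = 64
    z_threshold: float = 3.0
    pretrain_epochs: int = 0


class ClassifierBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden: tuple[int, int] = (128, 128)
    gamma: float = 0.9
    lr: float = 1e-3
    epochs: int = 30
    max_lag: float = 0.5


class EvaluationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    psnr_peak_mode: str = "max_abs_clean"


class CorruptionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    snr_db: float = 15.0
    line_freq: float = 50.0
    harmonic_fundamental: float = 10.0
    n_harmonics: int = 3


class PipelineConfig(BaseModel):
    """All stage parameter blocks plus the global seed and band edges."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0), "gamma": (30.0, 100.0),
        }
    )
    denoise: DenoiseBlock = Field(default_factory=DenoiseBlock)
    harmonics: HarmonicsBlock = Field(default_factory=HarmonicsBlock)
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    classifier: ClassifierBlock = Field(default_factory=ClassifierBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    corruption: CorruptionBlock = Field(default_factory=CorruptionBlock)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.model_validate(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(self.model_dump_json()), f, sort_keys=True)


# --------------------------------------------------------------------------
# Run logging
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunLogEntry:
    stage: str
    kind: str          # e.g. "loss", "mse"
    iteration: int
    value: float
    timestamp: float


@dataclass
class RunLog:
    """Iteration-indexed training/evaluation curves.

    Iteration indices must be strictly increasing per (stage, kind) and all
    values finite.
    """

    entries: list[RunLogEntry] = field(default_factory=list)

    def append(self, stage: str, kind: str, iteration: int, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"non-finite log value for {stage}/{kind}")
        last = self._last_iteration(stage, kind)
        if last is not None and iteration <= last:
            raise ValueError(
                f"iteration {iteration} not increasing for {stage}/{kind} (last {last})"
            )
        self.entries.append(RunLogEntry(stage, kind, iteration, float(value), time.time()))

    def _last_iteration(self, stage: str, kind: str) -> Optional[int]:
        for e in reversed(self.entries):
            if e.stage == stage and e.kind == kind:
                return e.iteration
        return None

    def extend_curve(self, stage: str, kind: str, values) -> None:
        start = self._last_iteration(stage, kind)
        start = -1 if start is None else start
        for i, v in enumerate(values):
            self.append(stage, kind, start + 1 + i, float(v))

    def curve(self, stage: str, kind: str) -> tuple[np.ndarray, np.ndarray]:
        pts = [(e.iteration, e.value) for e in self.entries if e.stage == stage and e.kind == kind]
        if not pts:
            return np.empty(0, dtype=int), np.empty(0)
        it, val = zip(*pts)
        return np.asarray(it), np.asarray(val)
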
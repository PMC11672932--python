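"""Classification and signal-quality metrics.

All classification metrics are derived from per-class one-vs-rest
TP/FP/FN/TN counts of a 4x4 confusion matrix (classes ordered
normal, mild, moderate, severe).  Scalar summaries are macro averages;
per-class values are always reported alongside.  The headline MCC uses the
multiclass covariance form; per-class one-vs-rest MCCs are also included.
Zero-denominator cells are defined as 0 and flagged, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import AnxietyLevel, EEGRecording

__all__ = [
    "CLASS_NAMES",
    "confusion",
    "classification_metrics",
    "MetricReport",
    "signal_quality",
    "SignalQualityReport",
    "mse",
    "mae",
    "psnr",
    "curve_logging",
    "read_curve_file",
]

CLASS_NAMES = tuple(lvl.label for lvl in AnxietyLevel)
N_CLASSES = len(CLASS_NAMES)


def _as_index(y) -> np.ndarray:
    out = np.asarray([int(AnxietyLevel(v)) for v in y], dtype=int)
    if out.size and (out.min() < 0 or out.max() >= N_CLASSES):
        raise ValueError("labels must encode the four anxiety levels 0-3")
    return out


def confusion(y_true: Sequence, y_pred: Sequence) -> np.ndarray:
    """4x4 confusion matrix; rows = true class, columns = predicted class."""
    t, p = _as_index(y_true), _as_index(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


@dataclass
class MetricReport:
    """Per-class and macro-averaged classification metrics for four classes."""

    confusion_matrix: np.ndarray
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    mcc_multiclass: float
    averaging: str = "macro one-vs-rest"
    degenerate_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mcc_multiclass": self.mcc_multiclass,
            "macro": dict(self.macro),
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "averaging": self.averaging,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "degenerate_flags": list(self.degenerate_flags),
        }


def classification_metrics(cm: np.ndarray) -> MetricReport:
    """Compute the full metric suite from a 4x4 confusion matrix.

    Per class i (one-vs-rest): TP = cm[i,i], FN = row_i - TP, FP = col_i - TP,
    TN = total - TP - FN - FP; then
    precision, sensitivity (recall), specificity, F1, NPV, MCC and the
    definitional complements FDR = 1 - precision, FPR = 1 - specificity,
    FNR = 1 - sensitivity.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (N_CLASSES, N_CLASSES) or np.any(cm < 0):
        raise ValueError("confusion matrix must be 4x4 with nonnegative counts")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    flags: list[str] = []
    accuracy = float(np.trace(cm)) / total

    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(CLASS_NAMES):
        tp = float(cm[i, i])
        fn = float(cm[i].sum() - tp)
        fp = float(cm[:, i].sum() - tp)
        tn = float(total - tp - fn - fp)
        precision = _safe_div(tp, tp + fp, flags, f"{name}:precision")
        sensitivity = _safe_div(tp, tp + fn, flags, f"{name}:sensitivity")
        specificity = _safe_div(tn, tn + fp, flags, f"{name}:specificity")
        f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, flags, f"{name}:f1")
        npv = _safe_div(tn, tn + fn, flags, f"{name}:npv")
        mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, f"{name}:mcc")
        per_class[name] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "f1": f1,
            "npv": npv,
            "mcc": mcc,
            "fdr": 1.0 - precision,
            "fpr": 1.0 - specificity,
            "fnr": 1.0 - sensitivity,
        }

    keys = ("precision", "sensitivity", "specificity", "f1", "npv", "mcc", "fdr", "fpr", "fnr")
    macro = {k: float(np.mean([per_class[c][k] for c in CLASS_NAMES])) for k in keys}
    macro["accuracy"] = accuracy

    # multiclass MCC, covariance form over the full 4x4 matrix
    t_k = cm.sum(axis=1).astype(float)
    p_k = cm.sum(axis=0).astype(float)
    c, s = float(np.trace(cm)), float(total)
    num = c * s - float(t_k @ p_k)
    den = math.sqrt((s * s - float(p_k @ p_k)) * (s * s - float(t_k @ t_k)))
    mcc_multi = _safe_div(num, den, flags, "mcc_multiclass")

    return MetricReport(
        confusion_matrix=cm,
        accuracy=accuracy,
        per_class=per_class,
        macro=macro,
        mcc_multiclass=mcc_multi,
        degenerate_flags=flags,
    )


def mse(clean: np.ndarray, estimate: np.ndarray) -> float:
    return float(np.mean((np.asarray(clean) - np.asarray(estimate)) ** 2))


def mae(clean: np.ndarray, estimate: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(clean) - np.asarray(estimate))))


def psnr(clean: np.ndarray, estimate: np.ndarray, peak: Optional[float] = None) -> float:
    """PSNR = 10 log10(peak^2 / MSE); peak defaults to max|clean|."""
    m = mse(clean, estimate)
    pk = float(np.max(np.abs(clean))) if peak is None else float(peak)
    if m == 0:
        return math.inf
    return 10 * math.log10(pk**2 / m)


@dataclass
class SignalQualityReport:
    mse_per_channel: np.ndarray
    mae_per_channel: np.ndarray
    psnr_per_channel: np.ndarray
    mse: float
    mae: float
    psnr: float
    peak_mode: str
    psnr_infinite: bool = False

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "psnr": None if self.psnr_infinite else self.psnr,
            "psnr_infinite": self.psnr_infinite,
            "peak_mode": self.peak_mode,
            "mse_per_channel": self.mse_per_channel.tolist(),
            "mae_per_channel": self.mae_per_channel.tolist(),
            "psnr_per_channel": [None if math.isinf(v) else v for v in self.psnr_per_channel],
        }


def signal_quality(
    clean: EEGRecording,
    estimate: EEGRecording,
    peak_mode: str = "max_abs_clean",
    peak_value: Optional[float] = None,
) -> SignalQualityReport:
    """Signal-fidelity report (MSE, MAE, PSNR) per channel and overall.

    EEG has no natural fixed peak, so the PSNR peak is max|clean| by default;
    pass ``peak_mode='constant'`` with ``peak_value`` to override.
    """
    if clean.data.shape != estimate.data.shape:
        raise ValueError("clean and estimate must share one shape")
    if peak_mode == "max_abs_clean":
        peak = float(np.max(np.abs(clean.data)))
    elif peak_mode == "constant":
        if peak_value is None:
            raise ValueError("peak_value required for peak_mode='constant'")
        peak = float(peak_value)
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    mses = np.array([mse(c, e) for c, e in zip(clean.data, estimate.data)])
    maes = np.array([mae(c, e) for c, e in zip(clean.data, estimate.data)])
    psnrs = np.array([math.inf if m == 0 else 10 * math.log10(peak**2 / m) for m in mses])
    overall_mse = float(np.mean((clean.data - estimate.data) ** 2))
    return SignalQualityReport(
        mse_per_channel=mses,
        mae_per_channel=maes,
        psnr_per_channel=psnrs,
        mse=overall_mse,
        mae=float(np.mean(np.abs(clean.data - estimate.data))),
        psnr=math.inf if overall_mse == 0 else 10 * math.log10(peak**2 / overall_mse),
        peak_mode=peak_mode,
        psnr_infinite=overall_mse == 0,
    )


def curve_logging(log, out_dir) -> list:
    """Write every (stage, kind) curve of a run log to a delimited file.

    Files are named ``<stage>_<kind>.csv`` with columns iteration,value —
    the machine-readable twin of training-loss / windowed-MSE figures.
    Returns the written paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = sorted({(e.stage, e.kind) for e in log.entries})
    written = []
    for stage, kind in pairs:
        it, val = log.curve(stage, kind)
        path = out_dir / f"{stage}_{kind}.csv"
        with open(path, "w") as f:
            f.write("iteration,value\n")
            for i, v in zip(it, val):
                f.write(f"{i},{float(v)!r}\n")
        written.append(path)
    return written


def read_curve_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Re-parse a curve file written by :func:`curve_logging`."""
    its, vals = [], []
    with open(path) as f:
        header = f.readline()
        if header.strip() != "iteration,value":
            raise ValueError(f"{path}: unexpected curve-file header")
        for line in f:
            if line.strip():
                i, v = line.strip().split(",")
                its.append(int(i))
                vals.append(float(v))
    return np.asarray(its, dtype=int), np.asarray(vals)
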
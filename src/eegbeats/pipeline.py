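"""End-to-end pipeline: cohort -> denoise -> harmonic subtraction ->
transient features -> band-lag Markov states -> DQN -> metric report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import (
    DQNAgent,
    DQNConfig,
    StateScaler,
    band_cross_correlation,
    build_state,
    train_dqn,
)
from .core import AnxietyLevel, Cohort, CohortSpec, EEGRecording
from .denoise import CAEConfig, CAEModel, WienerConfig, denoise, train_cae
from .harmonics import HarmonicConfig, HarmonicScorer, subtract_harmonics, train_harmonic_scorer
from .io import PipelineConfig, RunLog
from .metrics import MetricReport, classification_metrics, confusion
from .synthetic import corrupt, generate_cohort
from .transients import TransientConfig, TransientFeatureExtractor

logger = logging.getLogger("eegbeats")

__all__ = ["PipelineResult", "run_pipeline", "extract_states"]


@dataclass
class PipelineResult:
    report: MetricReport
    y_true: np.ndarray
    y_pred: np.ndarray
    agent: DQNAgent
    cae: CAEModel
    scorer: HarmonicScorer
    extractor: TransientFeatureExtractor
    scaler: StateScaler
    states: np.ndarray = None
    labels: np.ndarray = None
    train_idx: np.ndarray = None
    test_idx: np.ndarray = None
    log: RunLog = field(default_factory=RunLog)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


def _stage_configs(cfg: PipelineConfig):
    cae = CAEConfig(
        window=cfg.denoise.window, channels=tuple(cfg.denoise.channels),
        strides=tuple(cfg.denoise.strides), kernel=cfg.denoise.kernel,
        epochs=cfg.denoise.epochs, lr=cfg.denoise.lr,
    )
    wiener = WienerConfig(mode=cfg.denoise.mode, eps=cfg.denoise.eps,
                          psd_nperseg=cfg.denoise.psd_nperseg)
    harm = HarmonicConfig(
        mu_step=cfg.harmonics.mu_step, mu_refine=cfg.harmonics.mu_refine,
        attention_temperature=cfg.harmonics.attention_temperature,
        prominence_threshold=cfg.harmonics.prominence_threshold,
    )
    trans = TransientConfig(
        d_model=cfg.features.d_model, n_heads=cfg.features.n_heads,
        n_layers=cfg.features.n_layers, mem_len=cfg.features.mem_len,
        lstm_hidden=cfg.features.lstm_hidden, z_threshold=cfg.features.z_threshold,
        seed=cfg.seed,
    )
    dqn = DQNConfig(hidden=tuple(cfg.classifier.hidden), gamma=cfg.classifier.gamma,
                    lr=cfg.classifier.lr, epochs=cfg.classifier.epochs)
    return cae, wiener, harm, trans, dqn


def extract_states(
    records: Sequence[EEGRecording],
    cae: CAEModel,
    scorer: HarmonicScorer,
    extractor: TransientFeatureExtractor,
    wiener: WienerConfig,
    harm: HarmonicConfig,
    max_lag: float = 0.5,
) -> np.ndarray:
    """Run the three signal stages on each record and build raw state rows."""
    rows = []
    for rec in records:
        den = denoise(rec, cae, wiener)
        harmfree, _ = subtract_harmonics(den, scorer, harm)
        vec = extractor.record_vector(harmfree)
        lags = band_cross_correlation(harmfree, max_lag=max_lag)
        rows.append(np.concatenate([vec, lags.flatten()]))
    return np.asarray(rows)


def run_pipeline(
    spec: Optional[CohortSpec] = None,
    config: Optional[PipelineConfig] = None,
    cohort: Optional[Cohort] = None,
) -> PipelineResult:
    """Run the full chain on a synthetic cohort and score the test split.

    The cohort's clean recordings are corrupted per the config (broadband
    noise, mains line, harmonic train); the denoiser trains on a subset of
    the *clean* training split; every record then flows through denoising,
    harmonic subtraction, transient feature extraction and band-lag state
    construction; the DQN trains on the training split only.
    """
    config = config or PipelineConfig()
    if cohort is None:
        spec = spec or CohortSpec()
        cohort = generate_cohort(spec)
    cae_cfg, wiener, harm, trans, dqn_cfg = _stage_configs(config)
    log = RunLog()
    rng = np.random.default_rng(config.seed)

    logger.info("corrupting %d records", len(cohort.records))
    cb = config.corruption
    noisy = [
        corrupt(rec, cb.snr_db, line_freq=cb.line_freq,
                harmonic_fundamental=cb.harmonic_fundamental,
                n_harmonics=cb.n_harmonics, seed=int(rng.integers(2**31))).noisy
        for rec in cohort.records
    ]

    logger.info("training autoencoder on clean train records")
    clean_train = [cohort.records[i] for i in cohort.train_idx[:config.denoise.n_train_records]]
    cae = train_cae(clean_train, cae_cfg, seed=config.seed)
    log.extend_curve("denoise", "loss", cae.loss_curve)

    logger.info("training harmonic scorer")
    scorer = train_harmonic_scorer(
        n_samples=config.harmonics.scorer_samples,
        fs=cohort.spec.fs,
        epochs=config.harmonics.scorer_epochs,
        seed=config.seed,
    )
    extractor = TransientFeatureExtractor(trans)
    if config.features.pretrain_epochs > 0:
        logger.info("self-supervised feature pretraining")
        extractor.pretrain(clean_train, epochs=config.features.pretrain_epochs,
                           seed=config.seed)

    logger.info("extracting states")
    raw_states = extract_states(noisy, cae, scorer, extractor, wiener, harm,
                                max_lag=config.classifier.max_lag)
    labels = np.array([int(rec.label) for rec in cohort.records])

    scaler = StateScaler().fit(raw_states[cohort.train_idx])
    states = scaler.transform(raw_states)

    logger.info("training DQN")
    agent = train_dqn(states[cohort.train_idx], labels[cohort.train_idx],
                      dqn_cfg, seed=config.seed)
    log.extend_curve("classifier", "loss", agent.loss_curve)
    log.extend_curve("classifier", "reward", agent.reward_curve)

    y_true = labels[cohort.test_idx]
    y_pred = agent.predict(states[cohort.test_idx])
    report = classification_metrics(confusion(y_true, y_pred))
    logger.info("test accuracy %.3f", report.accuracy)
    return PipelineResult(
        report=report, y_true=y_true, y_pred=y_pred, agent=agent, cae=cae,
        scorer=scorer, extractor=extractor, scaler=scaler, states=states,
        labels=labels, train_idx=cohort.train_idx, test_idx=cohort.test_idx, log=log,
    )
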
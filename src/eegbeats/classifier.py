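"""Band-cross-correlated Markov deep-Q classification of anxiety level.

The classifier state for one recording concatenates (a) the fused transient
temporal features and (b) the flattened band-lag matrix: for every pair of
clinical bands, the signed time delay at peak normalized cross-correlation
and the peak value itself.  States are standardized with training-split
statistics only.  By construction the state carries all decision-relevant
information, so the decision process is Markov: each recording is one
one-step episode for a deep Q-network whose four actions are the anxiety
levels.  Reward is +1 for the correct class and -1 otherwise; the network
trains by mini-batch temporal-difference updates from a replay buffer
against a periodically synchronized target network, with an annealed
epsilon-greedy behaviour policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import DEFAULT_BANDS, AnxietyLevel, BandDefinition, EEGRecording
from .nn import Adam, Linear, Module, Tensor

__all__ = [
    "BandLagMatrix",
    "cross_correlate_signals",
    "band_cross_correlation",
    "StateScaler",
    "build_state",
    "DQNConfig",
    "DQNAgent",
    "train_dqn",
    "classify",
]


@dataclass
class BandLagMatrix:
    """Pairwise peak cross-correlation lags between band-filtered signals.

    ``lag[(i, j)]`` (seconds, signed) satisfies lag(i,j) = -lag(j,i);
    ``peak[(i, j)]`` is the normalized correlation at that lag, in [-1, 1].
    """

    band_names: list[str]
    lags: dict[tuple[int, int], float]
    peaks: dict[tuple[int, int], float]
    max_lag: float
    degenerate: set[int] = field(default_factory=set)

    def lag(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        return self.lags[(i, j)] if (i, j) in self.lags else -self.lags[(j, i)]

    def peak(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        return self.peaks[(i, j)] if (i, j) in self.peaks else self.peaks[(j, i)]

    def flatten(self) -> np.ndarray:
        """Unordered-pair (lag, peak) entries in a fixed order."""
        out = []
        for i, j in combinations(range(len(self.band_names)), 2):
            out.extend([self.lag(i, j), self.peak(i, j)])
        return np.asarray(out)


def cross_correlate_signals(
    signals: np.ndarray,
    fs: float,
    max_lag: float = 0.5,
    names: Optional[Sequence[str]] = None,
) -> BandLagMatrix:
    """Pairwise peak normalized cross-correlation of pre-extracted band signals.

    The normalized cross-correlation of every pair is searched over
    +-``max_lag`` seconds; ties break toward the smaller |lag|.  A
    zero-variance signal yields correlation 0 at lag 0 and a degenerate flag.
    """
    filtered = [np.asarray(s, dtype=float) for s in np.atleast_2d(signals)]
    names = list(names) if names is not None else [f"band{i}" for i in range(len(filtered))]
    n = len(filtered[0])
    if n <= 2 * max_lag * fs:
        raise ValueError("signals must be longer than twice max_lag")
    L = int(round(max_lag * fs))
    lags_s = np.arange(-L, L + 1) / fs
    lag_d: dict[tuple[int, int], float] = {}
    peak_d: dict[tuple[int, int], float] = {}
    degenerate: set[int] = set()
    stds = [float(np.std(f)) for f in filtered]
    for i in range(len(filtered)):
        if stds[i] == 0:
            degenerate.add(i)
    for i, j in combinations(range(len(filtered)), 2):
        if stds[i] == 0 or stds[j] == 0:
            lag_d[(i, j)] = 0.0
            peak_d[(i, j)] = 0.0
            continue
        a, b_ = filtered[i] - filtered[i].mean(), filtered[j] - filtered[j].mean()
        full = sps.correlate(a, b_, mode="full")
        mid = n - 1
        window = full[mid - L: mid + L + 1] / (n * stds[i] * stds[j])
        # correlate(a,b) peaks at -d when b is a delayed by d; negate so the
        # reported lag is the delay of band j relative to band i
        order = np.lexsort((np.abs(lags_s), -window))
        best = order[0]
        lag_d[(i, j)] = float(-lags_s[best])
        peak_d[(i, j)] = float(window[best])
    return BandLagMatrix(
        band_names=names,
        lags=lag_d, peaks=peak_d, max_lag=max_lag, degenerate=degenerate,
    )


def band_cross_correlation(
    rec: EEGRecording,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    max_lag: float = 0.5,
) -> BandLagMatrix:
    """Peak cross-correlation lags between the recording's clinical bands.

    Channels are averaged and each band is isolated with a zero-phase
    4th-order Butterworth band-pass before the pairwise correlation search.
    """
    if rec.duration <= 2 * max_lag:
        raise ValueError("recording must be longer than twice max_lag")
    fs = rec.fs
    x = rec.data.mean(axis=0)
    filtered = []
    for b in bands:
        b.validate_against(fs)
        sos = sps.butter(4, [max(b.low, 1e-3), min(b.high, 0.99 * fs / 2)],
                         btype="bandpass", fs=fs, output="sos")
        filtered.append(sps.sosfiltfilt(sos, x))
    return cross_correlate_signals(
        np.asarray(filtered), fs, max_lag, names=[b.name for b in bands]
    )


# --------------------------------------------------------------------------
# State construction
# --------------------------------------------------------------------------

class StateScaler:
    """Per-dimension standardization fitted on the training split only."""

    def __init__(self) -> None:
        self.mean: Optional[np.ndarray] = None
        self.std: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "StateScaler":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        # columns that are constant up to float error get unit scale
        degenerate = self.std <= 1e-9 * (np.abs(self.mean) + 1.0)
        self.std[degenerate] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mean) / self.std


def build_state(features: np.ndarray, lags: BandLagMatrix, scaler: StateScaler) -> np.ndarray:
    """Concatenate fused features with the flattened lag matrix and scale."""
    raw = np.concatenate([np.asarray(features, dtype=float).ravel(), lags.flatten()])
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite state features")
    return scaler.transform(raw[None, :])[0]


# --------------------------------------------------------------------------
# Deep Q-network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DQNConfig:
    hidden: tuple[int, int] = (128, 128)
    gamma: float = 0.9
    lr: float = 1e-3
    batch_size: int = 64
    replay_capacity: int = 10_000
    target_sync: int = 250
    eps_start: float = 1.0
    eps_end: float = 0.05
    epochs: int = 30


class _QNet(Module):
    def __init__(self, d_in: int, hidden: tuple[int, int], rng: np.random.Generator):
        self.l1 = Linear(d_in, hidden[0], rng)
        self.l2 = Linear(hidden[0], hidden[1], rng)
        self.out = Linear(hidden[1], 4, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.l2(self.l1(x).relu()).relu())


@dataclass
class DQNAgent:
    """Trained Q-network with its target twin and training curves."""

    net: _QNet
    target: _QNet
    config: DQNConfig
    d_in: int
    seed: int
    reward_curve: list[float] = field(default_factory=list)
    loss_curve: list[float] = field(default_factory=list)

    def q_values(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if states.shape[1] != self.d_in:
            raise ValueError(f"state dimension {states.shape[1]} != agent input {self.d_in}")
        return self.net(Tensor(states)).data

    def predict(self, states: np.ndarray) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return np.argmax(self.q_values(states), axis=1)

    def save(self, path, scaler: Optional[StateScaler] = None) -> None:
        extra = {}
        if scaler is not None and scaler.mean is not None:
            extra = {"scaler_mean": scaler.mean, "scaler_std": scaler.std}
        np.savez(
            path,
            d_in=np.array([self.d_in]),
            seed=np.array([self.seed]),
            hidden=np.asarray(self.config.hidden),
            gamma=np.array([self.config.gamma]),
            reward_curve=np.asarray(self.reward_curve),
            **{f"param_{i}": p for i, p in enumerate(self.net.state_dict())},
            **extra,
        )

    @classmethod
    def load(cls, path) -> tuple["DQNAgent", Optional[StateScaler]]:
        z = np.load(path)
        cfg = DQNConfig(hidden=tuple(int(h) for h in z["hidden"]), gamma=float(z["gamma"][0]))
        d_in, seed = int(z["d_in"][0]), int(z["seed"][0])
        rng = np.random.default_rng(seed)
        net = _QNet(d_in, cfg.hidden, rng)
        target = _QNet(d_in, cfg.hidden, rng)
        n = len(net.parameters())
        net.load_state_dict([z[f"param_{i}"] for i in range(n)])
        target.load_state_dict(net.state_dict())
        agent = cls(net=net, target=target, config=cfg, d_in=d_in, seed=seed,
                    reward_curve=list(z["reward_curve"]))
        scaler = None
        if "scaler_mean" in z:
            scaler = StateScaler()
            scaler.mean, scaler.std = z["scaler_mean"], z["scaler_std"]
        return agent, scaler


def train_dqn(
    states: np.ndarray,
    labels: Sequence,
    config: DQNConfig = DQNConfig(),
    seed: int = 0,
) -> DQNAgent:
    """Episodic Q-learning over the labelled training states.

    One episode is a pass over the shuffled training split.  At each step the
    epsilon-greedy agent picks an action (a class), receives +1/-1, and the
    transition is stored; mini-batches from the replay buffer drive
    temporal-difference updates against the target network.
    """
    X = np.asarray(states, dtype=float)
    y = np.asarray([int(AnxietyLevel(v)) for v in labels])
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("states must be (n, d) aligned with labels")
    counts = np.bincount(y, minlength=4)
    if np.any(counts < 2):
        raise ValueError("need at least 2 examples of every class")
    rng = np.random.default_rng(seed)
    net = _QNet(X.shape[1], config.hidden, rng)
    target = _QNet(X.shape[1], config.hidden, rng)
    target.load_state_dict(net.state_dict())
    opt = Adam(net.parameters(), lr=config.lr)

    buf_s = np.zeros((config.replay_capacity, X.shape[1]))
    buf_a = np.zeros(config.replay_capacity, dtype=int)
    buf_r = np.zeros(config.replay_capacity)
    buf_s2 = np.zeros((config.replay_capacity, X.shape[1]))
    buf_done = np.zeros(config.replay_capacity)
    buf_n, buf_ptr = 0, 0

    agent = DQNAgent(net=net, target=target, config=config, d_in=X.shape[1], seed=seed)
    step = 0
    total_steps = config.epochs * len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        ep_reward = 0.0
        for t, idx in enumerate(order):
            eps = config.eps_start + (config.eps_end - config.eps_start) * min(
                step / max(total_steps * 0.5, 1), 1.0
            )
            s = X[idx]
            if rng.random() < eps:
                a = int(rng.integers(4))
            else:
                a = int(np.argmax(net(Tensor(s[None, :])).data[0]))
            r = 1.0 if a == y[idx] else -1.0
            ep_reward += r
            nxt = X[order[(t + 1) % len(order)]]
            done = 1.0 if t == len(order) - 1 else 0.0
            buf_s[buf_ptr], buf_a[buf_ptr], buf_r[buf_ptr] = s, a, r
            buf_s2[buf_ptr], buf_done[buf_ptr] = nxt, done
            buf_ptr = (buf_ptr + 1) % config.replay_capacity
            buf_n = min(buf_n + 1, config.replay_capacity)
            step += 1

            if buf_n >= config.batch_size:
                bidx = rng.integers(0, buf_n, size=config.batch_size)
                q_next = target(Tensor(buf_s2[bidx])).data.max(axis=1)
                targets = buf_r[bidx] + config.gamma * (1.0 - buf_done[bidx]) * q_next
                q = net(Tensor(buf_s[bidx]))
                sel = q[np.arange(config.batch_size), buf_a[bidx]]
                loss = ((sel - Tensor(targets)) ** 2).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"DQN training diverged at step {step}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                agent.loss_curve.append(float(loss.data))
            if step % config.target_sync == 0:
                target.load_state_dict(net.state_dict())
        agent.reward_curve.append(ep_reward / len(X))
    target.load_state_dict(net.state_dict())
    return agent


def classify(agent: DQNAgent, state: np.ndarray) -> AnxietyLevel:
    """Greedy action for one state: argmax over the four Q-values."""
    return AnxietyLevel(int(agent.predict(np.atleast_2d(state))[0]))
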
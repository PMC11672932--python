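"""Layers and modules built on the autodiff engine."""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np

from .autodiff import Tensor, pad_last, unfold1d

__all__ = ["Module", "Linear", "Conv1d", "LayerNorm", "LSTMCell", "Sequential", "Upsample1d", "Relu", "Tanh"]


class Module:
    """Base class: collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        state = list(state)
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = math.sqrt(1.0 / d_in)
        self.W = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Conv1d(Module):
    """1-D convolution over (batch, channels, length), 'same' or 'valid' padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: str = "same",
    ):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        scale = math.sqrt(1.0 / (c_in * kernel))
        self.W = Tensor(rng.uniform(-scale, scale, size=(c_out, c_in * kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError("Conv1d expects (batch, channels, length)")
        if self.padding == "same":
            total = self.kernel - 1
            x = pad_last(x, total // 2, total - total // 2)
        B, C, _ = x.shape
        u = unfold1d(x, self.kernel, self.stride)          # (B, C, K, L_out)
        L_out = u.shape[-1]
        u = u.reshape(B, C * self.kernel, L_out).transpose(0, 2, 1)  # (B, L_out, C*K)
        out = u @ self.W.transpose() + self.b               # (B, L_out, c_out)
        return out.transpose(0, 2, 1)                       # (B, c_out, L_out)


class Upsample1d(Module):
    """Nearest-neighbour upsampling of the last axis by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        idx = np.repeat(np.arange(x.shape[-1]), self.factor)
        return x[..., idx]


class Relu(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class LSTMCell(Module):
    """Standard LSTM cell; the gated output is y = y_out * h(s_c) where s_c
    is the internal cell state and h a squashing nonlinearity."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.ih = Linear(d_in, 4 * d_hidden, rng)
        self.hh = Linear(d_hidden, 4 * d_hidden, rng, bias=False)
        self.d_hidden = d_hidden

    def forward(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = self.ih(x) + self.hh(h)
        d = self.d_hidden
        i = z[..., 0:d].sigmoid()
        f = z[..., d:2 * d].sigmoid()
        g = z[..., 2 * d:3 * d].tanh()
        o = z[..., 3 * d:4 * d].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new
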
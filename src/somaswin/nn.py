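"""Small neural-network layer library on top of :mod:`somaswin.autograd`.

Provides the handful of building blocks the transformer needs (linear maps,
layer norm, a two-layer MLP) plus an Adam optimiser.  Parameter
initialisation is driven by an explicit :class:`numpy.random.Generator` so
model construction is fully deterministic given a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class with recursive parameter discovery over attributes."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _collect(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        seen: set[int] = set()
        yield from _collect_named(self, prefix, seen)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect(value, seen: set[int]) -> Iterator[Tensor]:
    if isinstance(value, Tensor):
        if value.requires_grad and id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for sub in value.__dict__.values():
            yield from _collect(sub, seen)
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item, seen)


def _collect_named(obj, prefix: str, seen: set[int]) -> Iterator[tuple[str, Tensor]]:
    if isinstance(obj, Tensor):
        if obj.requires_grad and id(obj) not in seen:
            seen.add(id(obj))
            yield prefix, obj
    elif isinstance(obj, Module):
        for key, value in obj.__dict__.items():
            sub = f"{prefix}.{key}" if prefix else key
            yield from _collect_named(value, sub, seen)
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            yield from _collect_named(item, f"{prefix}.{i}", seen)


class Linear(Module):
    """Affine map on the last axis, truncated-normal weight init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        w = rng.normal(0.0, std, size=(in_features, out_features))
        np.clip(w, -2 * std, 2 * std, out=w)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = ag.add(y, self.bias)
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.weight, self.bias, self.eps)


class Mlp(Module):
    """Two-layer perceptron with GELU, the transformer feed-forward block."""

    def __init__(self, dim: int, hidden_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ag.gelu(self.fc1(x)))


class Adam:
    """Adam optimiser with decoupled weight decay (AdamW)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
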
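"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the shifted-window transformer and its
segmentation head need: broadcasted add/mul, batched matmul, reshape /
transpose / basic-slice indexing, cyclic roll, zero padding, concatenation,
nearest-neighbour upsampling, softmax, GELU, layer normalisation, embedding
lookup (for relative position bias tables) and a numerically stable binary
cross-entropy on logits.  Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar.

All tensors are float32; the graph is built eagerly and freed after the
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "matmul", "reshape", "transpose", "getitem",
    "roll2d", "pad", "concat", "upsample_nearest2d", "softmax", "gelu",
    "layer_norm", "embedding", "bce_with_logits", "mean",
]


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph; leaf grads remain
        for node in order:
            node._parents = ()
            node._backward = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    out_data = a.data.reshape(shape)

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    return Tensor(out_data, _parents=(a,), _backward=bw)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = np.transpose(a.data, axes)

    def bw(g):
        _accum(a, np.transpose(g, inv))

    return Tensor(out_data, _parents=(a,), _backward=bw)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return Tensor(out_data, _parents=(a,), _backward=bw)


def roll2d(a: Tensor, shift: tuple[int, int], axes: tuple[int, int] = (0, 1)) -> Tensor:
    out_data = np.roll(a.data, shift, axis=axes)
    inv = tuple(-s for s in shift)

    def bw(g):
        _accum(a, np.roll(g, inv, axis=axes))

    return Tensor(out_data, _parents=(a,), _backward=bw)


def pad(a: Tensor, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
    pad_width = tuple(tuple(p) for p in pad_width)
    out_data = np.pad(a.data, pad_width)
    crop = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, a.data.shape))

    def bw(g):
        _accum(a, g[crop])

    return Tensor(out_data, _parents=(a,), _backward=bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


def upsample_nearest2d(a: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of an (H, W, C) tensor by ``factor``."""
    f = int(factor)
    out_data = np.repeat(np.repeat(a.data, f, axis=0), f, axis=1)
    h, w, c = a.data.shape

    def bw(g):
        _accum(a, g.reshape(h, f, w, f, c).sum(axis=(1, 3)))

    return Tensor(out_data, _parents=(a,), _backward=bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(a, (g - dot) * y)

    return Tensor(y, _parents=(a,), _backward=bw)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(a: Tensor) -> Tensor:
    """GELU with the tanh approximation."""
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def bw(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        dt = (1.0 - t ** 2) * dinner
        _accum(a, g * (0.5 * (1.0 + t) + 0.5 * x * dt))

    return Tensor(y, _parents=(a,), _backward=bw)


def layer_norm(a: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    y = xhat * weight.data + bias.data

    def bw(g):
        if weight.requires_grad:
            _accum(weight, (g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            _accum(bias, g.reshape(-1, x.shape[-1]).sum(axis=0))
        if a.requires_grad:
            gw = g * weight.data
            m1 = gw.mean(axis=-1, keepdims=True)
            m2 = (gw * xhat).mean(axis=-1, keepdims=True)
            _accum(a, (gw - m1 - xhat * m2) * inv)

    return Tensor(y, _parents=(a, weight, bias), _backward=bw)


def embedding(table: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup ``table[index]``; gradients scatter-add into the table."""
    index = np.asarray(index)
    out_data = table.data[index]

    def bw(g):
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, index, g)

    return Tensor(out_data, _parents=(table,), _backward=bw)


def mean(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.mean(), dtype=np.float32)
    n = a.data.size

    def bw(g):
        _accum(a, np.full_like(a.data, g / n))

    return Tensor(out_data, _parents=(a,), _backward=bw)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_with_logits(logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy on logits, stable for large |x|.

    ``pos_weight`` scales the positive-class term, countering the heavy
    foreground/background imbalance of sparse soma masks.
    """
    t = np.asarray(targets, dtype=np.float32)
    x = logits.data
    w = np.float32(pos_weight)
    loss = w * t * _softplus(-x) + (1.0 - t) * _softplus(x)
    out_data = np.asarray(loss.mean(), dtype=np.float32)
    n = x.size

    def bw(g):
        grad = (-w * t * _sigmoid(-x) + (1.0 - t) * _sigmoid(x)) * (g / n)
        _accum(logits, grad)

    return Tensor(out_data, _parents=(logits,), _backward=bw)
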
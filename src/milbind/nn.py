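"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tensor/autograd engine providing exactly the primitives the
instance-scoring networks need: elementwise arithmetic with broadcasting,
matrix multiplication, valid cross-correlation along the width axis,
non-overlapping max-pooling, reductions, the usual nonlinearities, a
numerically stable log-softmax, inverted dropout, Glorot initialisation
and the AdaDelta optimiser.

Gradients are accumulated by a topological backward sweep from a scalar
loss.  All arrays are float32 (single precision is ample for SGD-style
training and halves memory traffic).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another tensor's gradient buffer
            self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar ------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])


class Parameter(Tensor):
    """A trainable leaf tensor; ``decay`` marks it for L2 weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


# -- elementwise -------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_holder: list[Tensor] = []

    def backward():
        out = out_holder[0]
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.shape))

    out = _make(a.data + b.data, (a, b), backward)
    out_holder.append(out)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_holder: list[Tensor] = []

    def backward():
        out = out_holder[0]
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.data, b.shape))

    out = _make(a.data * b.data, (a, b), backward)
    out_holder.append(out)
    return out


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_holder: list[Tensor] = []

    def backward():
        out = out_holder[0]
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(
                _unbroadcast(-out.grad * a.data / (b.data**2), b.shape)
            )

    out = _make(a.data / b.data, (a, b), backward)
    out_holder.append(out)
    return out


def _unary(a, fwd, grad_fn) -> Tensor:
    a = _as_tensor(a)
    value = fwd(a.data)
    out_holder: list[Tensor] = []

    def backward():
        out = out_holder[0]
        if a.requires_grad:
            a._accumulate(out.grad * grad_fn(a.data, value))

    out = _make(value, (a,), backward)
    out_holder.append(out)
    return out


def relu(a) -> Tensor:
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float))


def sigmoid(a) -> Tensor:
    return _unary(a, expit, lambda x, y: y * (1.0 - y))


def tanh(a) -> Tensor:
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def exp(a) -> Tensor:
    return _unary(a, np.exp, lambda x, y: y)


def log(a) -> Tensor:
    return _unary(a, np.log, lambda x, y: 1.0 / x)


# -- shape ops ---------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_holder: list[Tensor] = []

    def backward():
        if a.requires_grad:
            a._accumulate(out_holder[0].grad.reshape(a.shape))

    out = _make(a.data.reshape(shape), (a,), backward)
    out_holder.append(out)
    return out


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inverse = np.argsort(axes)
    out_holder: list[Tensor] = []

    def backward():
        if a.requires_grad:
            a._accumulate(out_holder[0].grad.transpose(inverse))

    out = _make(a.data.transpose(axes), (a,), backward)
    out_holder.append(out)
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out_holder: list[Tensor] = []

    def backward():
        pieces = np.split(out_holder[0].grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(g)

    out = _make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors), backward)
    out_holder.append(out)
    return out


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis
               for p in parts)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    basic = _is_basic_index(idx)
    out_holder: list[Tensor] = []

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            if basic:  # basic indexing never repeats elements
                g[idx] += out_holder[0].grad
            else:
                np.add.at(g, idx, out_holder[0].grad)
            a._accumulate(g)

    out = _make(a.data[idx], (a,), backward)
    out_holder.append(out)
    return out


# -- reductions --------------------------------------------------------


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_holder: list[Tensor] = []

    def backward():
        if a.requires_grad:
            g = out_holder[0].grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)
    out_holder.append(out)
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    value = a.data.max(axis=axis, keepdims=keepdims)
    out_holder: list[Tensor] = []

    def backward():
        if a.requires_grad:
            g = out_holder[0].grad
            v = value
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                v = np.expand_dims(v, axis)
            mask = (a.data == v).astype(float)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None \
                else mask.sum()
            a._accumulate(mask * g)

    out = _make(value, (a,), backward)
    out_holder.append(out)
    return out


# -- linear algebra ----------------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_holder: list[Tensor] = []

    def backward():
        out = out_holder[0]
        if a.requires_grad:
            a._accumulate(out.grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ out.grad)

    out = _make(a.data @ b.data, (a, b), backward)
    out_holder.append(out)
    return out


# -- network layers ----------------------------------------------------


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid cross-correlation along the last axis.

    x: (N, C, W); w: (F, C, K); b: (F,) -> (N, F, W-K+1).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, c, width = x.data.shape
    f, _, k = w.data.shape
    out_w = width - k + 1
    if out_w < 1:
        raise ValueError(
            f"convolution kernel ({k}) wider than input width ({width})"
        )
    # (N, C, out_w, K) strided window view — no copy
    windows = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=2)
    value = np.einsum("ncok,fck->nfo", windows, w.data,
                      optimize=True) + b.data[:, None]
    out_holder: list[Tensor] = []

    def backward():
        dout = out_holder[0].grad  # (N, F, out_w)
        if b.requires_grad:
            b._accumulate(dout.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate(np.einsum("nfo,ncok->fck", dout, windows,
                                    optimize=True))
        if x.requires_grad:
            dcols = np.einsum("nfo,fck->ncok", dout, w.data, optimize=True)
            dx = np.zeros_like(x.data)
            for kk in range(k):
                dx[:, :, kk:kk + out_w] += dcols[:, :, :, kk]
            x._accumulate(dx)

    out = _make(value, (x, w, b), backward)
    out_holder.append(out)
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max-pooling along the last axis; the right-edge
    remainder (width mod pool) is dropped."""
    x = _as_tensor(x)
    n, f, width = x.data.shape
    t = width // pool
    if t < 1:
        raise ValueError(f"pool width ({pool}) exceeds input width ({width})")
    trimmed = x.data[:, :, : t * pool].reshape(n, f, t, pool)
    idx = trimmed.argmax(axis=3)
    value = np.take_along_axis(trimmed, idx[..., None], axis=3)[..., 0]
    out_holder: list[Tensor] = []

    def backward():
        if x.requires_grad:
            g = np.zeros((n, f, t, pool))
            np.put_along_axis(g, idx[..., None], out_holder[0].grad[..., None],
                              axis=3)
            dx = np.zeros_like(x.data)
            dx[:, :, : t * pool] = g.reshape(n, f, t * pool)
            x._accumulate(dx)

    out = _make(value, (x,), backward)
    out_holder.append(out)
    return out


def global_maxpool1d(x: Tensor) -> Tensor:
    """Max over the whole width axis: (N, F, W) -> (N, F)."""
    return tmax(x, axis=2)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    value = shifted - logsumexp
    softmax = np.exp(value)
    out_holder: list[Tensor] = []

    def backward():
        dy = out_holder[0].grad
        if x.requires_grad:
            x._accumulate(dy - softmax * dy.sum(axis=axis, keepdims=True))

    out = _make(value, (x,), backward)
    out_holder.append(out)
    return out


def dropout(x: Tensor, ratio: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout: zero each unit with probability ``ratio`` during
    training and rescale survivors by 1/(1-ratio); identity at inference."""
    if not train or ratio <= 0.0:
        return _as_tensor(x)
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"dropout ratio must be in [0, 1), got {ratio}")
    mask = (rng.random(x.data.shape) >= ratio) / (1.0 - ratio)
    return mul(x, Tensor(mask))


# -- initialisation & optimisation ------------------------------------


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None,
                   fan_out: int | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation on the given shape."""
    if fan_in is None or fan_out is None:
        if len(shape) == 2:
            fan_in, fan_out = shape
        elif len(shape) == 3:  # conv kernels (F, C, K)
            receptive = shape[2]
            fan_in = shape[1] * receptive
            fan_out = shape[0] * receptive
        else:
            fan_in = fan_out = int(np.prod(shape))
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class AdaDelta:
    """AdaDelta with per-parameter accumulators.

    ``rho`` is the running-average momentum and ``eps`` the conditioning
    constant (the "delta"); ``lr`` scales the final update.  L2 weight
    decay is added to the gradient for parameters flagged ``decay``.
    """

    def __init__(self, params: dict[str, Parameter], lr: float = 1.0,
                 rho: float = 0.999, eps: float = 1e-4,
                 weight_decay: float = 5e-4):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self._eg2 = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._ed2 = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            eg2 = self._eg2[name]
            ed2 = self._ed2[name]
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            update = -np.sqrt(ed2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            ed2 *= self.rho
            ed2 += (1.0 - self.rho) * update * update
            p.data += self.lr * update
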
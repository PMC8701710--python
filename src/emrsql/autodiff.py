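"""Minimal reverse-mode automatic differentiation over numpy arrays.

The encoder-decoder in :mod:`emrsql.model` is small (two transformer
layers, one LSTM cell, a handful of pointer heads), so rather than pull in
a deep-learning framework the package carries this compact tape-based
engine: a :class:`Tensor` wraps an ``ndarray`` and records a backward
closure per operation; ``backward()`` walks the tape in reverse
topological order. The op set is exactly what the model needs — matmul,
elementwise nonlinearities, concat/narrow, gathers, layer norm and a
masked log-softmax — each with gradients verified against central finite
differences in the test suite.

Arrays keep whatever float dtype they are given (float32 for training,
float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "matmul", "tanh", "sigmoid", "relu", "scale",
    "concat", "narrow", "sum_", "mean_", "gather_rows", "gather_batch",
    "take_last", "masked_log_softmax", "masked_softmax", "log", "reshape",
    "transpose_last", "layer_norm",
    "Adam", "global_norm", "clip_grads_",
]

DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference paths)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(DEFAULT_DTYPE)
        self.data = arr
        self.grad = None
        self._grad_borrowed = False
        self.requires_grad = _GRAD_ENABLED and (
            requires_grad or any(p.requires_grad for p in parents)
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None
        self._grad_borrowed = False

    def _accumulate(self, g):
        # first contribution borrows the incoming buffer; a second one
        # forces a private copy before the in-place add
        if self.grad is None:
            if g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype)
                self._grad_borrowed = False
            else:
                self._grad_borrowed = True
            self.grad = g
        else:
            if self._grad_borrowed:
                self.grad = self.grad.copy()
                self._grad_borrowed = False
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` along broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def sub(a, b) -> Tensor:
    return add(a, scale(b, -1.0))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data * s, parents=(a,))

    def backward(g):
        a._accumulate(g * s)

    out._backward = backward if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            if b.data.ndim == 2 and a.data.ndim > 2:
                # batched input x shared weight: one flat GEMM instead of a
                # batched product followed by a sum over the batch axes
                k, n = b.data.shape
                gb = a.data.reshape(-1, k).T @ g.reshape(-1, n)
                b._accumulate(gb)
            else:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))

    def backward(g):
        a._accumulate(g * (1.0 - y * y))

    out._backward = backward if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, parents=(a,))

    def backward(g):
        a._accumulate(g * y * (1.0 - y))

    out._backward = backward if out.requires_grad else None
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def backward(g):
        a._accumulate(g * (a.data > 0))

    out._backward = backward if out.requires_grad else None
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, s0, s1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(s0, s1)
                t._accumulate(g[tuple(idx)])

    out._backward = backward if out.requires_grad else None
    return out


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = _as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = Tensor(a.data[idx], parents=(a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accumulate(full)

    out._backward = backward if out.requires_grad else None
    return out


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward if out.requires_grad else None
    return out


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def gather_rows(a, idx) -> Tensor:
    """Index along axis 0 (embedding lookup): out shape idx.shape + a.shape[1:]."""
    a = _as_tensor(a)
    idx = np.asarray(idx)
    out = Tensor(a.data[idx], parents=(a,))

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    out._backward = backward if out.requires_grad else None
    return out


def gather_batch(a, idx) -> Tensor:
    """Per-batch row pick along axis 1.

    a (B, N, ...) with idx (B,) -> (B, ...); idx (B, T) -> (B, T, ...).
    """
    a = _as_tensor(a)
    idx = np.asarray(idx)
    B = a.data.shape[0]
    if idx.ndim == 1:
        sel = (np.arange(B), idx)
    else:
        sel = (np.arange(B)[:, None], idx)
    out = Tensor(a.data[sel], parents=(a,))

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, sel, g)
        a._accumulate(full)

    out._backward = backward if out.requires_grad else None
    return out


def take_last(a, idx) -> Tensor:
    """Pick along the last axis: a (..., K), idx (...,) -> (...,)."""
    a = _as_tensor(a)
    idx = np.asarray(idx)
    out_data = np.take_along_axis(a.data, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(a,))

    def backward(g):
        full = np.zeros_like(a.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        a._accumulate(full)

    out._backward = backward if out.requires_grad else None
    return out


_NEG = -1e9  # finite stand-in for -inf so masked softmax stays nan-free


def masked_log_softmax(a, mask) -> Tensor:
    """Log-softmax over the last axis restricted to ``mask`` (bool array).

    Masked positions get log-probability ~-1e9 and zero gradient, so the
    probability over the admissible set sums to one and inadmissible
    actions carry exactly zero probability mass.
    """
    a = _as_tensor(a)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():  # fast path: nothing masked
        xmax = a.data.max(axis=-1, keepdims=True)
        z = np.exp(a.data - xmax)
        denom = z.sum(axis=-1, keepdims=True)
        logp = a.data - xmax - np.log(denom)
        softmax = z / denom
        out = Tensor(logp, parents=(a,))

        def backward_fast(g):
            a._accumulate(g - softmax * g.sum(axis=-1, keepdims=True))

        out._backward = backward_fast if out.requires_grad else None
        return out
    mask = np.broadcast_to(mask, a.data.shape)
    x = np.where(mask, a.data, _NEG)
    xmax = x.max(axis=-1, keepdims=True)
    z = np.exp(x - xmax)
    z = np.where(mask, z, 0.0)
    denom = z.sum(axis=-1, keepdims=True)
    denom = np.maximum(denom, 1e-30)
    logp = np.where(mask, x - xmax - np.log(denom), _NEG)
    softmax = z / denom
    out = Tensor(logp.astype(a.data.dtype), parents=(a,))

    def backward(g):
        g = np.where(mask, g, 0.0)
        dx = g - softmax * g.sum(axis=-1, keepdims=True)
        a._accumulate(np.where(mask, dx, 0.0).astype(a.data.dtype))

    out._backward = backward if out.requires_grad else None
    return out


def masked_softmax(a, mask) -> Tensor:
    """Softmax over the last axis restricted to ``mask``; masked entries 0."""
    a = _as_tensor(a)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():  # fast path: nothing masked
        xmax = a.data.max(axis=-1, keepdims=True)
        z = np.exp(a.data - xmax)
        s = z / z.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(a,))

        def backward_fast(g):
            a._accumulate(s * (g - (g * s).sum(axis=-1, keepdims=True)))

        out._backward = backward_fast if out.requires_grad else None
        return out
    mask = np.broadcast_to(mask, a.data.shape)
    x = np.where(mask, a.data, _NEG)
    xmax = x.max(axis=-1, keepdims=True)
    z = np.exp(x - xmax)
    z = np.where(mask, z, 0.0)
    denom = np.maximum(z.sum(axis=-1, keepdims=True), 1e-30)
    s = (z / denom).astype(a.data.dtype)
    out = Tensor(s, parents=(a,))

    def backward(g):
        dx = s * (g - (g * s).sum(axis=-1, keepdims=True))
        a._accumulate(np.where(mask, dx, 0.0).astype(a.data.dtype))

    out._backward = backward if out.requires_grad else None
    return out


def log(a, eps: float = 1e-12) -> Tensor:
    a = _as_tensor(a)
    clamped = np.maximum(a.data, eps)
    out = Tensor(np.log(clamped), parents=(a,))

    def backward(g):
        a._accumulate(g / clamped)

    out._backward = backward if out.requires_grad else None
    return out


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    out._backward = backward if out.requires_grad else None
    return out


def transpose_last(a) -> Tensor:
    """Swap the last two axes."""
    a = _as_tensor(a)
    out = Tensor(np.swapaxes(a.data, -1, -2), parents=(a,))

    def backward(g):
        a._accumulate(np.swapaxes(g, -1, -2))

    out._backward = backward if out.requires_grad else None
    return out


def layer_norm(a, gain, bias, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain/bias."""
    a, gain, bias = _as_tensor(a), _as_tensor(gain), _as_tensor(bias)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, parents=(a, gain, bias))
    d = a.data.shape[-1]

    def backward(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if a.requires_grad:
            gx = g * gain.data
            da = inv * (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            )
            a._accumulate(da.astype(a.data.dtype))

    out._backward = backward if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# optimization


def global_norm(params: dict[str, Tensor]) -> float:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    return float(np.sqrt(total))


def clip_grads_(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so the global norm is at most ``max_norm``."""
    norm = global_norm(params)
    if norm > max_norm and norm > 0:
        factor = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= factor
    return norm


class Adam:
    """Adaptive-moment optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
            p._grad_borrowed = False
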
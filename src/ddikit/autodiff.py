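"""Minimal reverse-mode automatic differentiation on numpy arrays.

Every operation in this module is *generic*: called on plain ``numpy``
arrays it returns a plain array, called on :class:`Tensor` (or a mix) it
returns a ``Tensor`` that records the computation on a tape.  The encoder
and loss code is therefore written once and serves both as the trainable
forward pass and as the plain-numpy evaluation path used by oracle tests.

The engine is deliberately small: dense arrays, float64, scalar backward
seed, no broadcasting tricks beyond numpy's own rules (gradients are
un-broadcast by summation).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "value",
    "add", "sub", "mul", "div", "neg", "power", "matmul",
    "exp", "log", "sqrt", "tanh", "sigmoid", "relu", "leaky_relu",
    "clip", "asum", "amean", "transpose", "reshape", "concatenate",
    "take", "dropout", "masked_softmax",
    "Adam", "cosine_lr", "finite_difference_grad", "max_relative_grad_error",
]


class Tensor:
    """A node on the differentiation tape wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "_parents", "_vjps")

    def __init__(self, data, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents  # tuple[Tensor]
        self._vjps = vjps        # tuple[Callable[[ndarray], ndarray]]

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, leaf={not self._parents})"

    # -- autodiff ------------------------------------------------------
    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order = _topo_order(self)
        self.grad = np.ones_like(self.data)
        for node in order:
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = np.array(contrib, dtype=np.float64, copy=True)
                else:
                    parent.grad = parent.grad + contrib

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, expo):
        return power(self, expo)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return asum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return amean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _topo_order(root: Tensor) -> list[Tensor]:
    """Reverse topological order via iterative DFS."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    order.reverse()
    return order


def parameter(data) -> Tensor:
    """Wrap an array as a trainable leaf tensor."""
    return Tensor(np.array(data, dtype=np.float64))


def value(x):
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, links):
    """Build a Tensor from (tensor, vjp) links, or a plain array if none."""
    links = [(t, v) for t, v in links if _is_t(t)]
    if not links:
        return data
    parents, vjps = zip(*links)
    return Tensor(data, parents=parents, vjps=vjps)


# ---------------------------------------------------------------------
# elementwise binary ops
# ---------------------------------------------------------------------

def add(a, b):
    da, db = value(a), value(b)
    out = da + db
    return _make(out, [
        (a, lambda g: _unbroadcast(g, da.shape)),
        (b, lambda g: _unbroadcast(g, db.shape)),
    ])


def sub(a, b):
    da, db = value(a), value(b)
    out = da - db
    return _make(out, [
        (a, lambda g: _unbroadcast(g, da.shape)),
        (b, lambda g: _unbroadcast(-g, db.shape)),
    ])


def mul(a, b):
    da, db = value(a), value(b)
    out = da * db
    return _make(out, [
        (a, lambda g: _unbroadcast(g * db, da.shape)),
        (b, lambda g: _unbroadcast(g * da, db.shape)),
    ])


def div(a, b):
    da, db = value(a), value(b)
    out = da / db
    return _make(out, [
        (a, lambda g: _unbroadcast(g / db, da.shape)),
        (b, lambda g: _unbroadcast(-g * da / (db * db), db.shape)),
    ])


def neg(a):
    return _make(-value(a), [(a, lambda g: -g)])


def power(a, expo: float):
    da = value(a)
    out = da ** expo
    return _make(out, [(a, lambda g: g * expo * da ** (expo - 1))])


def matmul(a, b):
    da, db = value(a), value(b)
    if da.ndim < 2 or db.ndim < 2:
        raise ValueError("matmul requires >=2-D operands")
    out = da @ db

    def grad_a(g):
        return _unbroadcast(g @ np.swapaxes(db, -1, -2), da.shape)

    def grad_b(g):
        return _unbroadcast(np.swapaxes(da, -1, -2) @ g, db.shape)

    return _make(out, [(a, grad_a), (b, grad_b)])


# ---------------------------------------------------------------------
# elementwise unary ops
# ---------------------------------------------------------------------

def exp(a):
    out = np.exp(value(a))
    return _make(out, [(a, lambda g: g * out)])


def log(a):
    da = value(a)
    return _make(np.log(da), [(a, lambda g: g / da)])


def sqrt(a):
    out = np.sqrt(value(a))
    return _make(out, [(a, lambda g: g * 0.5 / out)])


def tanh(a):
    out = np.tanh(value(a))
    return _make(out, [(a, lambda g: g * (1.0 - out * out))])


def sigmoid(a):
    da = value(a)
    out = np.where(da >= 0, 1.0 / (1.0 + np.exp(-np.clip(da, -500, None))),
                   np.exp(np.clip(da, None, 500)) / (1.0 + np.exp(np.clip(da, None, 500))))
    return _make(out, [(a, lambda g: g * out * (1.0 - out))])


def relu(a):
    da = value(a)
    mask = (da > 0).astype(np.float64)
    return _make(da * mask, [(a, lambda g: g * mask)])


def leaky_relu(a, slope: float = 0.2):
    da = value(a)
    scale = np.where(da > 0, 1.0, slope)
    return _make(da * scale, [(a, lambda g: g * scale)])


def clip(a, lo, hi):
    """Clamp; gradient is zero outside [lo, hi] (true subgradient)."""
    da = value(a)
    mask = ((da >= lo) & (da <= hi)).astype(np.float64)
    return _make(np.clip(da, lo, hi), [(a, lambda g: g * mask)])


# ---------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------

def asum(a, axis=None, keepdims=False):
    da = value(a)
    out = da.sum(axis=axis, keepdims=keepdims)

    def grad(g):
        if axis is None:
            return np.broadcast_to(g, da.shape).copy()
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, da.shape).copy()

    return _make(out, [(a, grad)])


def amean(a, axis=None, keepdims=False):
    da = value(a)
    n = da.size if axis is None else da.shape[axis]
    return div(asum(a, axis=axis, keepdims=keepdims), float(n))


def transpose(a, axes=None):
    da = value(a)
    if axes is None:
        axes = tuple(reversed(range(da.ndim)))
    inv = np.argsort(axes)
    return _make(np.transpose(da, axes), [(a, lambda g: np.transpose(g, inv))])


def reshape(a, shape):
    da = value(a)
    return _make(da.reshape(shape), [(a, lambda g: g.reshape(da.shape))])


def concatenate(parts: Sequence, axis: int = 0):
    datas = [value(p) for p in parts]
    out = np.concatenate(datas, axis=axis)
    links = []
    offset = 0
    for p, d in zip(parts, datas):
        n = d.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offset, offset + n)
        sl = tuple(sl)
        links.append((p, (lambda s: (lambda g: g[s]))(sl)))
        offset += n
    return _make(out, links)


def take(a, indices, axis: int = 0):
    """Gather along ``axis``; backward scatter-adds (handles repeats)."""
    da = value(a)
    idx = np.asarray(indices)
    out = np.take(da, idx, axis=axis)

    def grad(g):
        acc = np.zeros_like(da)
        if axis == 0:
            np.add.at(acc, idx, g)
        else:  # pragma: no cover - only axis 0 used
            sl = [slice(None)] * da.ndim
            for k, i in enumerate(idx):
                sl[axis] = i
                gsl = [slice(None)] * g.ndim
                gsl[axis] = k
                acc[tuple(sl)] += g[tuple(gsl)]
        return acc

    return _make(out, [(a, grad)])


def dropout(a, p: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when p == 0 or rng is None."""
    if p <= 0.0 or rng is None:
        return a
    da = value(a)
    mask = (rng.random(da.shape) >= p) / (1.0 - p)
    return mul(a, mask)


def masked_softmax(logits, mask, axis: int = -1):
    """Softmax restricted to ``mask`` (binary array); masked entries are 0.

    Rows with an all-zero mask would be undefined; callers guarantee every
    row has at least one admissible entry (e.g. via self-loop insertion).
    """
    mask = np.asarray(value(mask), dtype=np.float64)
    shift = np.max(np.where(mask > 0, value(logits), -np.inf),
                   axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)  # constant shift
    e = mul(exp(sub(logits, shift)), mask)
    return div(e, asum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------

class Adam:
    """Adam with decoupled L2 weight decay over a dict of parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self._t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1 ** self._t)
            vhat = self._v[k] / (1 - self.b2 ** self._t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, max_epochs: int) -> float:
    """Cosine annealing schedule from base_lr down to 0."""
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, max_epochs)))


# ---------------------------------------------------------------------
# gradient verification
# ---------------------------------------------------------------------

def finite_difference_grad(f: Callable[[np.ndarray], float], x: np.ndarray,
                           eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = float(f(x))
        flat[i] = orig - eps
        fm = float(f(x))
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def max_relative_grad_error(f: Callable, x: np.ndarray,
                            eps: float = 1e-5) -> float:
    """Compare analytic (tape) and finite-difference gradients of f at x.

    ``f`` must accept either a Tensor or an ndarray and return a scalar of
    the matching kind.  The relative error is normalized by the gradient
    magnitude scale to avoid division blow-ups near zero entries.
    """
    t = parameter(x)
    out = f(t)
    out.backward()
    analytic = t.grad
    numeric = finite_difference_grad(lambda a: float(value(f(a))), np.array(x))
    scale = max(np.abs(analytic).max(), np.abs(numeric).max(), 1e-8)
    return float(np.abs(analytic - numeric).max() / scale)
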
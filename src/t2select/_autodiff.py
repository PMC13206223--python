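"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the attention-based selector needs:
broadcasted arithmetic, (batched) matrix products, reductions, softmax,
layer normalization building blocks, embedding lookup, a numerically stable
binary cross-entropy with logits, and a batched inverse quadratic form
``d^T (S + ridge I)^{-1} d`` used by the differentiable Hotelling T-squared
loss.  Gradients are accumulated by topological-order backpropagation on a
dynamically built tape.

Every vector-Jacobian product here is validated against central finite
differences in the test suite; nothing in this module is specific to the
selector, but it is deliberately not a general-purpose framework.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data, parents, vjps) -> "Tensor":
        out = Tensor(data)
        live = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
        if live:
            out.requires_grad = True
            out._parents = tuple(p for p, _ in live)
            out._vjps = tuple(v for _, v in live)
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)
        }
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in zip(node._parents, node._vjps):
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def _coerce(self, other) -> "Tensor":
        """Wrap plain numbers at this tensor's dtype so python-float
        constants never upcast a float32 graph."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.shape),
                lambda g: _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g / other.data, self.shape),
                lambda g: _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data

        def vjp_a(g):
            return _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)

        def vjp_b(g):
            return _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)

        return Tensor._make(a @ b, (self, other), (vjp_a, vjp_b))

    def __getitem__(self, key) -> "Tensor":
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return out

        return Tensor._make(self.data[key], (self,), (vjp,))

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), (lambda g: g.reshape(old),)
        )

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), (self,), (lambda g: g.transpose(*inv),)
        )

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,)
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._make(out, (self,), (lambda g: g * out,))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), (lambda g: g * 0.5 / out,))

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), (lambda g: g * (1.0 - out**2),))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        return vjp

    return Tensor._make(
        np.concatenate(datas, axis=axis),
        tuple(tensors),
        tuple(make_vjp(i) for i in range(len(tensors))),
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    s = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=axis, keepdims=True)

    def vjp(g):
        out = g * s
        out -= s * out.sum(axis=axis, keepdims=True)
        return out

    return Tensor._make(s, (x,), (vjp,))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    phi = 0.5 * (1.0 + erf(x.data * 0.7071067811865476))
    dens = np.exp(-0.5 * x.data**2) * 0.3989422804014327
    out = x.data * phi

    def vjp(g):
        return g * (phi + x.data * dens)

    return Tensor._make(out, (x,), (vjp,))


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    out = expit(x.data)
    return Tensor._make(out, (x,), (lambda g: g * out * (1.0 - out),))


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of an embedding table; gradient scatter-adds."""
    idx = np.asarray(indices, dtype=int)

    def vjp(g):
        out = np.zeros_like(table.data)
        np.add.at(out, idx, g)
        return out

    return Tensor._make(table.data[idx], (table,), (vjp,))


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale+shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    scale = (var + Tensor(np.asarray(eps, dtype=x.data.dtype))).sqrt()
    return centered / scale * gain + bias


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, computed stably from raw logits.

    L = mean( softplus(z) - y*z ) with softplus(z) = log(1 + e^z) evaluated
    as max(z,0) + log1p(e^{-|z|}).
    """
    z = logits.data
    y = np.asarray(targets).astype(z.dtype)
    sp = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    loss = np.asarray(np.mean(sp - y * z), dtype=z.dtype)
    from scipy.special import expit

    def vjp(g):
        return (g * (expit(z) - y) / z.size).astype(z.dtype)

    return Tensor._make(loss, (logits,), (vjp,))


def batched_inv_quad(delta: Tensor, cov: Tensor, ridge: float) -> Tensor:
    """``q_j = delta_j^T (cov_j + ridge I)^{-1} delta_j`` for each batch j.

    ``cov`` must be symmetric per batch element (as pooled covariances are).
    Gradients: dq/d(delta) = 2 y, dq/d(cov) = -y y^T with
    y = (cov + ridge I)^{-1} delta.
    """
    d = delta.data  # (..., k)
    S = cov.data  # (..., k, k)
    k = d.shape[-1]
    M = S + ridge * np.eye(k, dtype=S.dtype)
    y = np.linalg.solve(M, d[..., None])[..., 0]
    q = np.einsum("...k,...k->...", d, y)

    def vjp_delta(g):
        return 2.0 * g[..., None] * y

    def vjp_cov(g):
        return -g[..., None, None] * (y[..., :, None] * y[..., None, :])

    return Tensor._make(q, (delta, cov), (vjp_delta, vjp_cov))
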
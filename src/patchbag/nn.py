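"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the patch-response encoder and
the gating branch need: strided valid 3D convolution, 3D max pooling,
instance normalization, ReLU/sigmoid/log point-wise maps, reductions, and an
Adam optimizer.  Feature maps are stored channel-first as ``(C, X, Y, Z)``
float32 arrays; gradients are accumulated by :meth:`Tensor.backward` in
reverse topological order.

Everything here is deterministic: given the same inputs and parameter
values, forward and backward passes are bit-reproducible (single-threaded
numpy, no atomics).
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "tsum",
    "tmean",
    "channel_mean",
    "conv3d",
    "maxpool3d",
    "instance_norm",
    "crop_center",
    "he_normal",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable | None = None,
        name: str | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar by default) node's output."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar; every operator routes through the module functions so
    # there is a single implementation of each derivative.
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

    def __repr__(self):  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag}, name={self.name})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None or t._parents for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, out_data, da: Callable, db: Callable) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if not _needs_grad(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(da(g), a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(db(g), b.data.shape))

    out._backward = backward
    return out


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(
        a,
        b,
        a.data / b.data,
        lambda g: g / b.data,
        lambda g: -g * a.data / (b.data * b.data),
    )


def neg(a):
    a = as_tensor(a)
    return _binary(a, Tensor(0.0), -a.data, lambda g: -g, lambda g: np.zeros(()))


def _unary(a, out_data, da: Callable) -> Tensor:
    a = as_tensor(a)
    if not _needs_grad(a):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a,))
    out._backward = lambda g: a._accumulate(da(g))
    return out


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _unary(a, a.data * mask, lambda g: g * mask)


def sigmoid(a):
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    s = s.astype(np.float32)
    return _unary(a, s, lambda g: g * s * (1.0 - s))


def log(a):
    a = as_tensor(a)
    return _unary(a, np.log(a.data), lambda g: g / a.data)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient passes only where no clamping occurred."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return _unary(a, np.clip(a.data, lo, hi), lambda g: g * mask)


def tsum(a):
    a = as_tensor(a)
    return _unary(a, a.data.sum(), lambda g: np.broadcast_to(g, a.data.shape))


def tmean(a):
    a = as_tensor(a)
    n = a.data.size
    return _unary(a, a.data.mean(), lambda g: np.broadcast_to(g / n, a.data.shape))


def channel_mean(a):
    """Mean over the channel axis of a (C, X, Y, Z) map -> (X, Y, Z)."""
    a = as_tensor(a)
    c = a.data.shape[0]
    return _unary(
        a,
        a.data.mean(axis=0),
        lambda g: np.broadcast_to(g[None] / c, a.data.shape),
    )


# ---------------------------------------------------------------------------
# spatial layers


def conv3d(x, w, b=None, stride: int = 1) -> Tensor:
    """Valid (zero-padding-free) strided 3D convolution.

    ``x`` is ``(C_in, X, Y, Z)``, ``w`` is ``(C_out, C_in, k, k, k)`` with an
    odd isotropic kernel, ``b`` an optional ``(C_out,)`` bias.  Output is
    ``(C_out, x', y', z')`` with ``n' = floor((n - k)/stride) + 1``.
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, *ext = x.data.shape
    cout, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel expects {cin_w}")
    if any(n < k for n in ext):
        raise ValueError(f"input extent {tuple(ext)} smaller than kernel {k}")
    s = int(stride)

    if k == 1 and s == 1:
        # point-wise fast path: a per-voxel linear map over channels
        out_data = np.tensordot(w.data[:, :, 0, 0, 0], x.data, axes=(1, 0))
        if b is not None:
            out_data = out_data + as_tensor(b).data.reshape(-1, 1, 1, 1)
        parents = (x, w) if b is None else (x, w, as_tensor(b))
        out = Tensor(out_data, parents=parents)

        def backward_pw(g):
            w2 = w.data[:, :, 0, 0, 0]
            if x.requires_grad or x._parents:
                x._accumulate(np.tensordot(w2.T, g, axes=(1, 0)))
            if w.requires_grad:
                gw = np.tensordot(g.reshape(cout, -1), x.data.reshape(cin, -1).T, axes=1)
                w._accumulate(gw.reshape(w.data.shape))
            if b is not None and parents[2].requires_grad:
                parents[2]._accumulate(g.sum(axis=(1, 2, 3)))

        out._backward = backward_pw
        return out

    win = sliding_window_view(x.data, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
    ox, oy, oz = win.shape[1:4]
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        ox * oy * oz, cin * k**3
    )
    wmat = w.data.reshape(cout, -1)
    out_data = (cols @ wmat.T).T.reshape(cout, ox, oy, oz)
    if b is not None:
        out_data = out_data + as_tensor(b).data.reshape(-1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    out = Tensor(out_data, parents=parents)

    def backward(g):
        gflat = g.reshape(cout, -1)
        if w.requires_grad:
            w._accumulate((gflat @ cols).reshape(w.data.shape))
        if b is not None and parents[2].requires_grad:
            parents[2]._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad or x._parents:
            gx = np.zeros_like(x.data)
            for a_, b_, c_ in itertools.product(range(k), repeat=3):
                contrib = np.tensordot(w.data[:, :, a_, b_, c_], g, axes=(0, 0))
                gx[:, a_ : a_ + s * ox : s, b_ : b_ + s * oy : s, c_ : c_ + s * oz : s] += contrib
            x._accumulate(gx)

    out._backward = backward
    return out


def maxpool3d(x, kernel: int = 3, stride: int = 2) -> Tensor:
    """Valid 3D max pooling over (C, X, Y, Z)."""
    x = as_tensor(x)
    k, s = int(kernel), int(stride)
    c, *ext = x.data.shape
    if any(n < k for n in ext):
        raise ValueError(f"input extent {tuple(ext)} smaller than pooling kernel {k}")
    win = sliding_window_view(x.data, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
    ox, oy, oz = win.shape[1:4]
    wf = win.reshape(c, ox, oy, oz, k**3)
    arg = wf.argmax(axis=-1)
    out_data = np.take_along_axis(wf, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not (x.requires_grad or x._parents):
            return
        da, rem = np.divmod(arg, k * k)
        db, dc = np.divmod(rem, k)
        ii, jj, ll = np.meshgrid(
            np.arange(ox), np.arange(oy), np.arange(oz), indexing="ij"
        )
        ax = s * ii[None] + da
        ay = s * jj[None] + db
        az = s * ll[None] + dc
        _, X, Y, Z = x.data.shape
        flat = (ax * Y + ay) * Z + az
        ch = np.broadcast_to(np.arange(c)[:, None, None, None], flat.shape)
        gx = np.zeros((c, X * Y * Z), dtype=np.float32)
        np.add.at(gx, (ch.ravel(), flat.ravel()), g.ravel())
        x._accumulate(gx.reshape(x.data.shape))

    out._backward = backward
    return out


def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-channel standardization over the spatial axes with affine params.

    ``gamma`` and ``beta`` have shape ``(C,)``; statistics are computed per
    instance, per channel — there are no running averages, so train and eval
    behave identically.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    c = x.data.shape[0]
    xr = x.data.reshape(c, -1)
    # float64 accumulators: keeps the statistics independent of traversal
    # order, so translation equivariance holds to float32 precision
    mu = xr.mean(axis=1, keepdims=True, dtype=np.float64).astype(np.float32)
    var = xr.var(axis=1, keepdims=True, dtype=np.float64).astype(np.float32)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (xr - mu) * inv
    out_data = (gamma.data[:, None] * xn + beta.data[:, None]).reshape(x.data.shape)
    out = Tensor(out_data, parents=(x, gamma, beta))
    n = xr.shape[1]

    def backward(g):
        gr = g.reshape(c, -1)
        if gamma.requires_grad:
            gamma._accumulate((gr * xn).sum(axis=1))
        if beta.requires_grad:
            beta._accumulate(gr.sum(axis=1))
        if x.requires_grad or x._parents:
            gxn = gr * gamma.data[:, None]
            t1 = gxn.sum(axis=1, keepdims=True)
            t2 = (gxn * xn).sum(axis=1, keepdims=True)
            gx = inv / n * (n * gxn - t1 - xn * t2)
            x._accumulate(gx.reshape(x.data.shape))

    out._backward = backward
    return out


def crop_center(x, margin: int) -> Tensor:
    """Trim ``margin`` voxels from both ends of every spatial axis.

    Aligns an identity shortcut with the output of valid-padding 3^3
    convolutions inside a residual block.
    """
    x = as_tensor(x)
    if margin == 0:
        return x
    m = int(margin)
    sl = (slice(None), slice(m, -m), slice(m, -m), slice(m, -m))
    out = Tensor(x.data[sl], parents=(x,))

    def backward(g):
        if x.requires_grad or x._parents:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x._accumulate(gx)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# initialization and optimization


def he_normal(rng: np.random.Generator, shape: Sequence[int], fan_in: int) -> np.ndarray:
    """He (Kaiming) normal init: N(0, sqrt(2/fan_in)), float32."""
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Adam:
    """Adam with externally supplied per-step learning rate."""

    def __init__(
        self,
        params: Iterable[Tensor],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(np.float32)
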
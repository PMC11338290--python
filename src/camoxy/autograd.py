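"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the SpO2 regression networks need: broadcasted
arithmetic, matmul, the usual activations, reductions, shape manipulation,
slicing/concatenation, dropout, and an im2col-based N-d convolution (conv1d and
conv2d are routed through the 3-d kernel with singleton axes).  Gradients flow
through a tape built dynamically; ``Tensor.backward()`` runs a topological
sweep.  Everything is float64-by-default NumPy — small and deterministic rather
than fast, which is exactly what a CPU test rig wants.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "dropout", "batch_norm", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic info ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def pow(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    __pow__ = pow

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- activations --------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1 - y))

        return Tensor._make(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - y * y))

        return Tensor._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * y)

        return Tensor._make(y, (self,), backward)

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                np.add.at(gg, key, g)
                self._accum(gg)

        return Tensor._make(self.data[key], (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-p) at train time."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


# ---------------------------------------------------------------------------
# im2col-based 3-d convolution
# ---------------------------------------------------------------------------


def _pad3(x: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    pd, ph, pw = pad
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


def _im2col(x: np.ndarray, ksize, stride):
    """(N, C, D, H, W) -> columns (N, Do*Ho*Wo, C*kd*kh*kw) plus output dims."""
    from numpy.lib.stride_tricks import sliding_window_view

    kd, kh, kw = ksize
    sd, sh, sw = stride
    win = sliding_window_view(x, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::sd, ::sh, ::sw]  # (N, C, Do, Ho, Wo, kd, kh, kw)
    N, C, Do, Ho, Wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N, Do * Ho * Wo, C * kd * kh * kw)
    return np.ascontiguousarray(cols), (Do, Ho, Wo)


def _col2im(cols: np.ndarray, xshape, ksize, stride, outdims) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of column gradients)."""
    N, C, D, H, W = xshape
    kd, kh, kw = ksize
    sd, sh, sw = stride
    Do, Ho, Wo = outdims
    g = cols.reshape(N, Do, Ho, Wo, C, kd, kh, kw).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    x = np.zeros(xshape, dtype=cols.dtype)
    for a in range(kd):
        for b in range(kh):
            for c in range(kw):
                x[:, :, a : a + Do * sd : sd, b : b + Ho * sh : sh, c : c + Wo * sw : sw] += g[
                    ..., a, b, c
                ]
    return x


def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: tuple[int, int, int] = (1, 1, 1),
    padding: tuple[int, int, int] = (0, 0, 0),
) -> Tensor:
    """3-d convolution (cross-correlation): x (N,C,D,H,W), weight (F,C,kd,kh,kw)."""
    xp = _pad3(x.data, padding)
    F = weight.data.shape[0]
    ksize = weight.data.shape[2:]
    cols, outdims = _im2col(xp, ksize, stride)
    N = x.data.shape[0]
    P = cols.shape[1]
    K = cols.shape[2]
    flat = cols.reshape(N * P, K)
    Wmat = weight.data.reshape(F, -1)
    out = flat @ Wmat.T  # (N*P, F)
    if bias is not None:
        out = out + bias.data[None, :]
    Do, Ho, Wo = outdims
    out = out.reshape(N, P, F).transpose(0, 2, 1).reshape(N, F, Do, Ho, Wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gflat = np.ascontiguousarray(
            g.reshape(N, F, P).transpose(0, 2, 1)
        ).reshape(N * P, F)
        if bias is not None and bias.requires_grad:
            bias._accum(gflat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((gflat.T @ flat).reshape(weight.data.shape))
        if x.requires_grad:
            gx_cols = (gflat @ Wmat).reshape(N, P, K)
            gxp = _col2im(gx_cols, xp.shape, ksize, stride, outdims)
            pd, ph, pw = padding
            D, H, W = x.data.shape[2:]
            x._accum(gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W])

    return Tensor._make(out, parents, backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    eps: float = 1e-5,
    mean: np.ndarray | None = None,
    var: np.ndarray | None = None,
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalisation over axis 1, reducing over all other axes.

    With ``mean``/``var`` given (inference), normalises by those statistics;
    otherwise uses batch statistics.  Returns ``(y, mean, var)`` with the
    statistics as plain per-feature arrays.  The fused analytic backward
    avoids the large temporaries a primitive-composed implementation creates.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = (1, x.data.shape[1]) + (1,) * (x.data.ndim - 2)
    use_batch_stats = mean is None
    if use_batch_stats:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    mu = mean.reshape(shape)
    std = np.sqrt(var.reshape(shape) + eps)
    xhat = (x.data - mu) / std
    y = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)
    N = x.data.size // x.data.shape[1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(shape)
            if use_batch_stats:
                s1 = dxhat.sum(axis=axes).reshape(shape)
                s2 = (dxhat * xhat).sum(axis=axes).reshape(shape)
                x._accum((dxhat - s1 / N - xhat * s2 / N) / std)
            else:
                x._accum(dxhat / std)

    return Tensor._make(y, (x, gamma, beta), backward), mean, var
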
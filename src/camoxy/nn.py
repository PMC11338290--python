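"""Network layers and optimisation built on :mod:`camoxy.autograd`.

Provides the building blocks for the SpO2 regressors: 1/2/3-d convolutions,
linear layers, batch normalisation, dropout, an LSTM, residual 3-d blocks and
the Adam optimiser.  All randomness (initialisation, dropout masks) flows from
a single ``numpy`` Generator so training runs are reproducible bit-for-bit.
Initialisation is He-style for convolutions/linear layers.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, batch_norm, concat, conv3d, dropout

__all__ = [
    "Module",
    "Conv3d",
    "Conv2d",
    "Conv1d",
    "Linear",
    "BatchNorm",
    "InputNorm",
    "Dropout",
    "LSTM",
    "GlobalAvgPool3d",
    "BasicBlock3d",
    "Adam",
]


class Module:
    """Tiny module base: tracks parameters and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mk}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        for mk, m in self._named_buffers():
            d[mk] = m.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for k, v in d.items():
            if k in params:
                params[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unknown parameter '{k}'")

    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in getattr(self, "_buffers", {}):
            yield f"{prefix}{k}", getattr(self, "_buffers")[k]
        for mk, m in self._modules.items():
            yield from m._named_buffers(prefix=f"{prefix}{mk}.")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    std = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


def _triple(v) -> tuple[int, int, int]:
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


class Conv3d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_ch * int(np.prod(self.kernel))
        self.weight = _he_init(rng, (out_ch, in_ch) + self.kernel, fan_in)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Conv2d(Module):
    """2-d convolution expressed as a depth-1 3-d convolution: x (N, C, H, W)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        k = tuple(kernel) if isinstance(kernel, (tuple, list)) else (kernel, kernel)
        s = tuple(stride) if isinstance(stride, (tuple, list)) else (stride, stride)
        p = tuple(padding) if isinstance(padding, (tuple, list)) else (padding, padding)
        self.inner = Conv3d(in_ch, out_ch, (1,) + k, (1,) + s, (0,) + p, bias, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        y = self.inner(x.reshape(N, C, 1, H, W))
        _, F, _, Ho, Wo = y.shape
        return y.reshape(N, F, Ho, Wo)


class Conv1d(Module):
    """1-d convolution along the last axis: x (N, C, L)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        self.inner = Conv3d(in_ch, out_ch, (1, 1, kernel), (1, 1, stride), (0, 0, padding), bias, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, L = x.shape
        y = self.inner(x.reshape(N, C, 1, 1, L))
        _, F, _, _, Lo = y.shape
        return y.reshape(N, F, Lo)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalisation over axis 1 (features), reducing over all other axes."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features, dtype=np.float32), requires_grad=True)
        object.__setattr__(self, "_buffers", {
            "running_mean": np.zeros(n_features),
            "running_var": np.ones(n_features),
        })

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            y, mu, var = batch_norm(x, self.gamma, self.beta, self.eps)
            rb = self._buffers
            rb["running_mean"] *= 1 - self.momentum
            rb["running_mean"] += self.momentum * mu
            rb["running_var"] *= 1 - self.momentum
            rb["running_var"] += self.momentum * var
        else:
            y, _, _ = batch_norm(x, self.gamma, self.beta, self.eps,
                                 mean=self._buffers["running_mean"],
                                 var=self._buffers["running_var"])
        return y


class InputNorm(Module):
    """Parameter-free per-channel standardisation of the network input.

    Balances channels of very different magnitude (e.g. tiny pulsatile AC
    signals against large DC trends) without adding learnable parameters or a
    gradient path — the network input carries no gradient, so normalising
    outside the autodiff graph keeps the first convolution's backward cheap.
    Batch statistics are used during training and accumulated into running
    statistics for inference, batch-norm style.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        object.__setattr__(self, "_buffers", {
            "running_mean": np.zeros(n_features),
            "running_var": np.ones(n_features),
        })

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.data.ndim))
        shape = (1, x.data.shape[1]) + (1,) * (x.data.ndim - 2)
        rb = self._buffers
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            rb["running_mean"] *= 1 - self.momentum
            rb["running_mean"] += self.momentum * mu
            rb["running_var"] *= 1 - self.momentum
            rb["running_var"] += self.momentum * var
        else:
            mu, var = rb["running_mean"], rb["running_var"]
        out = (x.data - mu.reshape(shape)) / np.sqrt(var.reshape(shape) + self.eps)
        return Tensor(out.astype(x.data.dtype, copy=False))


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class LSTM(Module):
    """Single-layer LSTM over x (N, T, I); returns the final hidden state (N, H)."""

    def __init__(self, input_size: int, hidden_size: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        k = math.sqrt(1.0 / hidden_size)
        self.w_ih = Tensor(rng.uniform(-k, k, size=(input_size, 4 * hidden_size)).astype(np.float32), requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(4 * hidden_size, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class GlobalAvgPool3d(Module):
    """Mean over the temporal and both spatial axes: (N, C, D, H, W) -> (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3, 4))


class BasicBlock3d(Module):
    """Two 3x3x3 convolutions with batch norm and an (optionally projected) skip."""

    def __init__(self, in_ch, out_ch, stride=(1, 1, 1), rng=None):
        super().__init__()
        stride = _triple(stride)
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm(out_ch)
        self.needs_proj = stride != (1, 1, 1) or in_ch != out_ch
        if self.needs_proj:
            self.proj = Conv3d(in_ch, out_ch, 1, stride, 0, bias=False, rng=rng)
            self.proj_bn = BatchNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        skip = self.proj_bn(self.proj(x)) if self.needs_proj else x
        return (y + skip).relu()


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999) with optional decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled decay
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
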
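"""SpO2 regression networks and their training loop.

The primary regressor is a 3-d ResNet: a spatio-temporal stem convolution with
kernel [7,7,7], four residual stages with [3,3,3] kernels and standard channel
doubling, global average pooling over all three spatio-temporal axes, and a
two-layer fully connected head with dropout in between.  The sigmoid output in
[0, 1] is mapped linearly onto a configurable SpO2 range; rounding to integer
percent is the only post-processing.  Training minimises MSE with Adam, with
dropout and early stopping on a validation split to prevent overfitting.

Alongside the 3-d CNN, five baseline feature-extraction strategies are
available for comparison experiments:

* A — spatial averaging to per-channel signals, shallow 1-d CNN (temporal only);
* B — the same averaged signals fed per time step into an LSTM;
* C — blockwise spatial averages stacked into a signal image, shallow 2-d CNN;
* D — blockwise signals through a per-time-step 1-d CNN, then an LSTM;
* E — per-frame 2-d CNN spatial features, then an LSTM over frames.

Every strategy ends in the same sigmoid-scaled scalar head, so predictions are
directly comparable.

``tiny3d`` is a width-reduced two-stage variant of the ResNet pattern sized so
a CPU can train it in minutes; it follows the same stem/residual/pool/head
layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .autograd import Tensor, no_grad
from .preprocess import Observation
from .series import SpO2Series

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SpO2Regressor",
    "build_model",
    "build_baseline",
    "train",
    "predict",
    "save_model",
    "load_model",
]

ARCHITECTURES = (
    "resnet10_3d",
    "resnet18_3d",
    "resnet34_3d",
    "tiny3d",
    "strategyA",
    "strategyB",
    "strategyC",
    "strategyD",
    "strategyE",
)

_RESNET_BLOCKS = {"resnet10_3d": (1, 1, 1, 1), "resnet18_3d": (2, 2, 2, 2), "resnet34_3d": (3, 4, 6, 3)}


@dataclass
class ModelConfig:
    architecture: str = "tiny3d"
    in_channels: int = 10
    width: int = 64  # base channel count of the first ResNet stage
    dropout: float = 0.3
    scale_range: tuple[float, float] = (0.0, 100.0)  # sigmoid output -> SpO2 %
    block_grid: tuple[int, int] = (5, 5)  # used by strategies C/D
    input_scale: float = 255.0  # full-scale gray value used to normalise inputs
    input_pool: int = 1  # spatial average-pool factor applied in the input transform
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture '{self.architecture}'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        lo, hi = self.scale_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("scale range must satisfy 0 <= lo < hi <= 100")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.15
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class _ResNet3d(nn.Module):
    def __init__(self, in_ch, blocks, width, dropout, rng, stem_kernel=(7, 7, 7),
                 stem_stride=(1, 2, 2), head_hidden=64):
        super().__init__()
        pad = tuple(k // 2 for k in stem_kernel)
        self.in_bn = nn.InputNorm(in_ch)  # balances tiny AC against large DC channels
        self.stem = nn.Conv3d(in_ch, width, stem_kernel, stem_stride, pad, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm(width)
        chans = [width, 2 * width, 4 * width, 8 * width]
        stages = []
        in_c = width
        for si, (n_blocks, out_c) in enumerate(zip(blocks, chans)):
            for bi in range(n_blocks):
                stride = (2, 2, 2) if (si > 0 and bi == 0) else (1, 1, 1)
                stages.append(nn.BasicBlock3d(in_c, out_c, stride, rng=rng))
                in_c = out_c
        for i, blk in enumerate(stages):
            setattr(self, f"block{i}", blk)
        self.n_stage_blocks = len(stages)
        self.pool = nn.GlobalAvgPool3d()
        self.fc1 = nn.Linear(in_c, head_hidden, rng=rng)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Linear(head_hidden, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem_bn(self.stem(self.in_bn(x))).relu()
        for i in range(self.n_stage_blocks):
            y = getattr(self, f"block{i}")(y)
        y = self.pool(y)
        y = self.drop(self.fc1(y).relu())
        return self.fc2(y).sigmoid()


class _Tiny3d(nn.Module):
    """Width-reduced two-stage variant of the stem/residual/pool/head pattern."""

    def __init__(self, in_ch, dropout, rng, width=8):
        super().__init__()
        self.in_bn = nn.InputNorm(in_ch)  # balances tiny AC against large DC channels
        self.stem = nn.Conv3d(in_ch, width, (3, 5, 5), (2, 5, 5), (1, 2, 2), bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm(width)
        self.block0 = nn.BasicBlock3d(width, 2 * width, (1, 2, 2), rng=rng)
        self.block1 = nn.BasicBlock3d(2 * width, 2 * width, (2, 2, 2), rng=rng)
        self.pool = nn.GlobalAvgPool3d()
        self.fc1 = nn.Linear(2 * width, 16, rng=rng)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Linear(16, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem_bn(self.stem(self.in_bn(x))).relu()
        y = self.block1(self.block0(y))
        y = self.pool(y)
        y = self.drop(self.fc1(y).relu())
        return self.fc2(y).sigmoid()


class _ScalarHead(nn.Module):
    def __init__(self, in_features, hidden, dropout, rng):
        super().__init__()
        self.fc1 = nn.Linear(in_features, hidden, rng=rng)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Linear(hidden, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu())).sigmoid()


class _Strategy1dCNN(nn.Module):  # strategy A
    def __init__(self, in_ch, dropout, rng):
        super().__init__()
        self.c1 = nn.Conv1d(in_ch, 16, 3, padding=1, rng=rng)
        self.c2 = nn.Conv1d(16, 16, 3, padding=1, rng=rng)
        self.head = _ScalarHead(16, 16, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:  # x (N, C, 15)
        y = self.c2(self.c1(x).relu()).relu()
        return self.head(y.mean(axis=2))


class _StrategyLSTM(nn.Module):  # strategy B
    def __init__(self, in_ch, dropout, rng, hidden=32):
        super().__init__()
        self.lstm = nn.LSTM(in_ch, hidden, rng=rng)
        self.head = _ScalarHead(hidden, 16, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:  # x (N, C, 15)
        return self.head(self.lstm(x.transpose((0, 2, 1))))


class _Strategy2dCNN(nn.Module):  # strategy C
    def __init__(self, dropout, rng):
        super().__init__()
        self.c1 = nn.Conv2d(1, 8, 3, stride=(2, 1), padding=1, rng=rng)
        self.c2 = nn.Conv2d(8, 16, 3, stride=(2, 1), padding=1, rng=rng)
        self.head = _ScalarHead(16, 16, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:  # x (N, C*mn, 15) as a signal image
        N, R, L = x.shape
        y = self.c2(self.c1(x.reshape(N, 1, R, L)).relu()).relu()
        return self.head(y.mean(axis=(2, 3)))


class _Strategy1dCNNLSTM(nn.Module):  # strategy D
    def __init__(self, in_ch, dropout, rng, hidden=32):
        super().__init__()
        self.c1 = nn.Conv1d(1, 8, 5, stride=2, padding=2, rng=rng)
        self.in_ch = in_ch
        self.feat = 8 * ((in_ch + 1) // 2)
        self.lstm = nn.LSTM(self.feat, hidden, rng=rng)
        self.head = _ScalarHead(hidden, 16, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:  # x (N, C*mn, 15)
        N, R, L = x.shape
        # per-time-step spatial 1-d convolution over the blockwise signal vector
        z = x.transpose((0, 2, 1)).reshape(N * L, 1, R)
        z = self.c1(z).relu().reshape(N, L, self.feat)
        return self.head(self.lstm(z))


class _Strategy2dCNNLSTM(nn.Module):  # strategy E
    def __init__(self, in_ch, dropout, rng, hidden=32):
        super().__init__()
        self.c1 = nn.Conv2d(in_ch, 8, 5, stride=4, padding=2, rng=rng)
        self.c2 = nn.Conv2d(8, 16, 3, stride=2, padding=1, rng=rng)
        self.lstm = nn.LSTM(16, hidden, rng=rng)
        self.head = _ScalarHead(hidden, 16, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:  # x (N, C, 15, h, w)
        N, C, L, H, W = x.shape
        z = x.transpose((0, 2, 1, 3, 4)).reshape(N * L, C, H, W)
        z = self.c2(self.c1(z).relu()).relu()
        z = z.mean(axis=(2, 3)).reshape(N, L, 16)
        return self.head(self.lstm(z))


# ---------------------------------------------------------------------------
# input transforms
# ---------------------------------------------------------------------------


def _masked_spatial_mean(vol: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """(C, 15, h, w) -> (C, 15) mean over valid pixels (holes excluded)."""
    if mask is None or mask.all():
        return vol.mean(axis=(2, 3))
    m = mask.astype(float)
    return (vol * m).sum(axis=(2, 3)) / m.sum()


def _blockwise_mean(vol: np.ndarray, mask: np.ndarray | None, grid: tuple[int, int]) -> np.ndarray:
    """(C, 15, h, w) -> (C*m*n, 15) blockwise spatial means, holes excluded."""
    C, L, h, w = vol.shape
    m, n = grid
    bh, bw = h // m, w // n
    if bh < 1 or bw < 1:
        raise ValueError(f"block grid {grid} too fine for {h}x{w} observation")
    v = vol[:, :, : m * bh, : n * bw].reshape(C, L, m, bh, n, bw)
    if mask is None:
        mk = np.ones((m, bh, n, bw))
    else:
        mk = mask[: m * bh, : n * bw].reshape(m, bh, n, bw).astype(float)
    cnt = np.maximum(mk.sum(axis=(1, 3)), 1.0)
    means = (v * mk[None, None]).sum(axis=(3, 5)) / cnt[None, None]
    return means.transpose(0, 2, 3, 1).reshape(C * m * n, L)


# ---------------------------------------------------------------------------
# regressor wrapper
# ---------------------------------------------------------------------------


@dataclass
class SpO2Regressor:
    """A network plus its input transform and SpO2 output scaling."""

    net: nn.Module
    config: ModelConfig
    transform: Callable[[Observation], np.ndarray]

    def batch(self, observations: Sequence[Observation]) -> np.ndarray:
        return np.stack([self.transform(o) for o in observations]).astype(np.float32)

    def forward_raw(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in [0, 1] for a pre-transformed batch."""
        out = self.net(Tensor(x))
        return out.data.reshape(-1)

    def scale(self, raw: np.ndarray) -> np.ndarray:
        lo, hi = self.config.scale_range
        return lo + (hi - lo) * np.asarray(raw)

    def unscale(self, spo2: np.ndarray) -> np.ndarray:
        lo, hi = self.config.scale_range
        return (np.asarray(spo2, dtype=float) - lo) / (hi - lo)


def _volume_transform(cfg: ModelConfig) -> Callable[[Observation], np.ndarray]:
    pool = max(int(cfg.input_pool), 1)

    def tf(o: Observation) -> np.ndarray:
        vol = np.asarray(o.volume, dtype=np.float32) / cfg.input_scale
        if pool > 1:
            C, L, h, w = vol.shape
            hp, wp = (h // pool) * pool, (w // pool) * pool
            vol = vol[:, :, :hp, :wp].reshape(C, L, hp // pool, pool, wp // pool, pool)
            vol = vol.mean(axis=(3, 5))
        return vol

    return tf


def build_model(config: ModelConfig) -> SpO2Regressor:
    """Build the 3-d CNN regressor named by ``config.architecture``.

    Raises for baseline strategy names — those go through :func:`build_baseline`.
    """
    rng = np.random.default_rng(config.seed)
    if config.architecture in _RESNET_BLOCKS:
        net = _ResNet3d(config.in_channels, _RESNET_BLOCKS[config.architecture],
                        config.width, config.dropout, rng)
    elif config.architecture == "tiny3d":
        net = _Tiny3d(config.in_channels, config.dropout, rng)
    elif config.architecture.startswith("strategy"):
        return build_baseline(config.architecture[-1], config)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(f"unknown architecture '{config.architecture}'")
    return SpO2Regressor(net, config, _volume_transform(config))


def build_baseline(strategy: str, config: ModelConfig) -> SpO2Regressor:
    """Build one of the A–E baseline regressors plus its input transform."""
    strategy = strategy.upper()
    rng = np.random.default_rng(config.seed)
    scale = config.input_scale
    if strategy in ("A", "B"):
        def tf(o: Observation) -> np.ndarray:
            return _masked_spatial_mean(np.asarray(o.volume, float), o.pixel_mask) / scale

        net = (_Strategy1dCNN(config.in_channels, config.dropout, rng) if strategy == "A"
               else _StrategyLSTM(config.in_channels, config.dropout, rng))
    elif strategy in ("C", "D"):
        grid = config.block_grid

        def tf(o: Observation) -> np.ndarray:
            return _blockwise_mean(np.asarray(o.volume, float), o.pixel_mask, grid) / scale

        rows = config.in_channels * grid[0] * grid[1]
        net = (_Strategy2dCNN(config.dropout, rng) if strategy == "C"
               else _Strategy1dCNNLSTM(rows, config.dropout, rng))
    elif strategy == "E":
        def tf(o: Observation) -> np.ndarray:
            return np.asarray(o.volume, float) / scale

        net = _Strategy2dCNNLSTM(config.in_channels, config.dropout, rng)
    else:
        raise ValueError(f"unknown strategy '{strategy}'")
    cfg = ModelConfig(**{**asdict(config), "architecture": f"strategy{strategy}",
                         "scale_range": tuple(config.scale_range),
                         "block_grid": tuple(config.block_grid)})
    return SpO2Regressor(net, cfg, tf)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1
    seed: int = 0


def train(
    model: SpO2Regressor,
    observations: Sequence[Observation],
    cfg: TrainConfig,
) -> TrainHistory:
    """Fit the regressor with MSE loss, Adam, and early stopping.

    Labels are scaled into [0, 1] by the model's scaling range.  Training stops
    when validation MSE has not improved for ``cfg.patience`` epochs; the
    best-validation weights are restored before returning.
    """
    labelled = [o for o in observations if o.label is not None]
    if not labelled:
        raise ValueError("no labelled observations to train on")
    labels = np.array([o.label for o in labelled], dtype=float)
    if labels.min() < 0 or labels.max() > 100:
        raise ValueError("labels must be SpO2 percentages in [0, 100]")
    lo, hi = model.config.scale_range
    if labels.min() < lo or labels.max() > hi:
        raise ValueError(
            f"labels outside the model scale range [{lo}, {hi}]; widen scale_range"
        )
    X = model.batch(labelled)
    y = model.unscale(labels)
    rng = np.random.default_rng(cfg.seed)
    n = len(labelled)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = order, order
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[val_idx], y[val_idx]
    del X  # the split copies are all that is needed from here on
    opt = nn.Adam(model.net.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    hist = TrainHistory(seed=cfg.seed)
    best = np.inf
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    for epoch in range(cfg.max_epochs):
        model.net.train()
        perm = rng.permutation(len(tr_idx))
        losses = []
        for s in range(0, len(perm), cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            model.net.zero_grad()
            out = model.net(Tensor(Xtr[idx]))
            err = out.reshape(-1) - Tensor(ytr[idx])
            loss = (err * err).mean()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.net.eval()
        with no_grad():
            pv = model.forward_raw(Xva) if len(val_idx) else model.forward_raw(Xtr)
            vl = float(np.mean((pv - (yva if len(val_idx) else ytr)) ** 2))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(vl)
        if vl < best - 1e-12:
            best = vl
            best_state = model.net.state_dict()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if since_best >= cfg.patience:
            break
    hist.stopped_epoch = len(hist.val_loss) - 1
    if best_state is not None:
        model.net.load_state_dict(best_state)
    model.net.eval()
    return hist


def predict(model: SpO2Regressor, observations: Sequence[Observation],
            batch_size: int = 64) -> SpO2Series:
    """Predict integer-percent SpO2 per observation (rounded half-up).

    Timestamps are carried from the observations' start times.
    """
    model.net.eval()
    outs = []
    with no_grad():
        for s in range(0, len(observations), batch_size):
            chunk = observations[s : s + batch_size]
            outs.append(model.forward_raw(model.batch(chunk)))
    raw = np.concatenate(outs) if outs else np.empty(0)
    spo2 = np.floor(model.scale(raw) + 0.5).astype(int)  # round half-up
    times = np.array([o.start_time for o in observations])
    order = np.argsort(times)
    return SpO2Series(times[order], spo2[order])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def config_hash(*cfgs) -> str:
    blob = json.dumps([asdict(c) for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_model(path: str | Path, model: SpO2Regressor, seed: int | None = None) -> None:
    meta = {"config": asdict(model.config), "config_hash": config_hash(model.config),
            "seed": seed}
    state = {f"param::{k}": v for k, v in model.net.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta, default=str), **state)


def load_model(path: str | Path) -> SpO2Regressor:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg = meta["config"]
    cfg["scale_range"] = tuple(cfg["scale_range"])
    cfg["block_grid"] = tuple(cfg["block_grid"])
    model = build_model(ModelConfig(**cfg))
    state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    model.net.load_state_dict(state)
    model.net.eval()
    return model
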
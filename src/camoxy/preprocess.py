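"""Spatial-temporal preprocessing of multimodal ROI videos.

The registered forehead ROI video ``V`` (five channels: R, G, B, NIR 780, NIR
940 at 15 Hz) is spatially partitioned into ``m x n`` blocks of size
``(floor(h/m), floor(w/n))`` (residual right/bottom pixels discarded).  For each
block and channel the spatial-mean time series is fitted with a cubic
``P(t) = a t^3 + b t^2 + c t + d`` by ordinary least squares; the video then
decomposes exactly into a *trend* part ``T(x,y,t) = P(t)`` (spatially constant
within a block — the DC analogue of contact oximetry) and a *detrended* part
``B'(x,y,t) = B(x,y,t) - P(t)`` (the pulsatile AC analogue).  Both parts are
sliced into non-overlapping 1-s, 15-frame windows; the concatenation of a
detrended window and its trend window (10 channels total) with the 1 Hz
reference value at the window's start second forms one *observation*, the input
to the regression model.

A whole recording is a weak domain for a single cubic, so the fit is applied on
consecutive segments (default 30 s); ``segment_s=None`` selects the literal
whole-recording fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import SpO2Series

__all__ = [
    "RoiVideo",
    "BlockGrid",
    "BlockTrend",
    "DecomposedVideo",
    "Observation",
    "CHANNEL_ORDER",
    "partition_blocks",
    "fit_block_trend",
    "decompose_video",
    "slice_observations",
    "shift_reference",
    "select_channels",
]

logger = logging.getLogger(__name__)

CHANNEL_ORDER = ("r", "g", "b", "nir780", "nir940")


@dataclass
class RoiVideo:
    """Registered multimodal ROI video: ``data`` is ``(C, T, h, w)`` at 15 Hz."""

    data: np.ndarray
    channels: tuple[str, ...]
    fps: float
    timestamps: np.ndarray
    holes: np.ndarray  # (h, w) bool
    frame_invalid_fraction: np.ndarray | None = None
    qc_flagged_frames: list[int] = field(default_factory=list)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (C, T, h, w) matching the channel list")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size != self.data.shape[1]:
            raise ValueError("timestamps must match the frame count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI video values must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


@dataclass
class BlockGrid:
    m: int
    n: int
    block_size: tuple[int, int]
    index_map: np.ndarray  # (h, w) int, -1 on the discarded margin
    margin_mask: np.ndarray  # (h, w) bool, True where discarded

    @property
    def n_blocks(self) -> int:
        return self.m * self.n

    @property
    def covered_shape(self) -> tuple[int, int]:
        return self.m * self.block_size[0], self.n * self.block_size[1]


@dataclass
class BlockTrend:
    """Cubic trend coefficients (a, b, c, d) per block per channel for one segment."""

    coefficients: np.ndarray  # (C, m*n, 4)
    start_frame: int
    n_frames: int
    start_time: float


@dataclass
class DecomposedVideo:
    """Trend + detrended decomposition of the block-covered ROI video.

    ``trend + detrended`` reconstructs the input exactly; the trend is spatially
    constant within each block at each frame.
    """

    trend: np.ndarray  # (C, T, H', W')
    detrended: np.ndarray  # (C, T, H', W')
    channels: tuple[str, ...]
    grid: BlockGrid
    fps: float
    timestamps: np.ndarray
    pixel_mask: np.ndarray  # (H', W') bool, True where usable
    dropped_blocks: np.ndarray  # (m*n,) bool
    trends: list[BlockTrend] = field(default_factory=list)
    bit_depth: int = 8

    @property
    def n_frames(self) -> int:
        return self.trend.shape[1]


@dataclass
class Observation:
    """One model input: 1 s of detrended-then-trend channels plus its label.

    ``volume`` is ``(2C, 15, h', w')`` — detrended channels first, trend channels
    second, each in R, G, B, 780, 940 order.
    """

    volume: np.ndarray
    label: int | None
    start_time: float
    pixel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float32)
        if self.volume.shape[1] != 15:
            raise ValueError("an observation has exactly 15 frames")
        if self.label is not None and not (0 <= self.label <= 100):
            raise ValueError("label must be an SpO2 percentage in [0, 100]")


def partition_blocks(h: int, w: int, m: int, n: int) -> BlockGrid:
    """Partition an ``h x w`` ROI into ``m x n`` floor-sized disjoint blocks.

    Blocks are anchored at the top-left; residual right/bottom margins are
    discarded.  Block index is row-major: block ``(i, j)`` has index ``i*n + j``.
    """
    if not (1 <= m <= h and 1 <= n <= w):
        raise ValueError(f"invalid grid {m}x{n} for ROI {h}x{w}")
    bh, bw = h // m, w // n
    index_map = np.full((h, w), -1, dtype=int)
    rows = np.arange(m * bh) // bh
    cols = np.arange(n * bw) // bw
    index_map[: m * bh, : n * bw] = rows[:, None] * n + cols[None, :]
    margin = index_map < 0
    return BlockGrid(m, n, (bh, bw), index_map, margin)


def _cubic_design(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.stack([t**3, t**2, t, np.ones_like(t)], axis=1)


def fit_block_trend(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """OLS cubic fit of a block's spatial-mean time series.

    ``times`` are seconds from the segment start.  Returns ``(a, b, c, d)``.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size != times.size:
        raise ValueError("series / times length mismatch")
    if series.size < 4:
        raise ValueError("cubic fit needs at least 4 frames")
    coef, *_ = np.linalg.lstsq(_cubic_design(times), series, rcond=None)
    return coef


def _segment_bounds(T: int, fps: float, segment_s: float | None) -> list[tuple[int, int]]:
    if segment_s is None:
        return [(0, T)]
    seg = max(int(round(segment_s * fps)), 4)
    bounds = []
    start = 0
    while start < T:
        stop = min(start + seg, T)
        if T - stop < 4 and stop < T:
            stop = T  # absorb a tail too short to fit
        bounds.append((start, stop))
        start = stop
    # a leading segment shorter than 4 frames cannot be fitted
    if bounds and bounds[0][1] - bounds[0][0] < 4:
        raise ValueError("segment shorter than 4 frames")
    return bounds


def decompose_video(
    roi: RoiVideo,
    grid: BlockGrid,
    segment_s: float | None = 30.0,
    max_block_hole_fraction: float = 0.5,
) -> DecomposedVideo:
    """Blockwise cubic detrending of the ROI video into trend + detrended parts.

    Holes are excluded from the block spatial means; a block that is more than
    ``max_block_hole_fraction`` holes is dropped and its pixels masked out.
    The additive reconstruction ``trend + detrended == input`` is exact on the
    block-covered region.
    """
    C, T = roi.data.shape[:2]
    h, w = roi.shape
    if grid.index_map.shape != (h, w):
        raise ValueError("block grid does not match the ROI shape")
    Hc, Wc = grid.covered_shape
    bh, bw = grid.block_size
    m, n = grid.m, grid.n
    video = roi.data[:, :, :Hc, :Wc]
    holes = roi.holes[:Hc, :Wc]
    # (C, T, m, bh, n, bw) view for blockwise reductions
    blocks = video.reshape(C, T, m, bh, n, bw)
    hole_blocks = holes.reshape(m, bh, n, bw)
    good = ~hole_blocks
    counts = good.sum(axis=(1, 3)).astype(float)  # (m, n)
    hole_frac = 1.0 - counts / (bh * bw)
    dropped = (hole_frac > max_block_hole_fraction).reshape(-1)
    safe_counts = np.where(counts > 0, counts, 1.0)
    # spatial means over valid pixels only: (C, T, m, n)
    sums = (blocks * good[None, None]).sum(axis=(3, 5))
    means = sums / safe_counts[None, None]
    trend = np.empty_like(video)
    trends: list[BlockTrend] = []
    for start, stop in _segment_bounds(T, roi.fps, segment_s):
        t = roi.timestamps[start:stop] - roi.timestamps[start]
        X = _cubic_design(t)
        pinv = np.linalg.pinv(X)
        seg_means = means[:, start:stop]  # (C, L, m, n)
        flat = seg_means.reshape(C, stop - start, m * n)
        coef = np.einsum("kl,clb->cbk", pinv, flat)  # (C, m*n, 4)
        fitted = np.einsum("lk,cbk->clb", X, coef)  # (C, L, m*n)
        fitted = fitted.reshape(C, stop - start, m, n)
        trend[:, start:stop] = np.repeat(np.repeat(fitted, bh, axis=2), bw, axis=3)
        trends.append(BlockTrend(coef, start, stop - start, float(roi.timestamps[start])))
    detrended = video - trend
    pixel_mask = ~holes
    if dropped.any():
        drop_map = dropped.reshape(m, n)
        drop_px = np.repeat(np.repeat(drop_map, bh, axis=0), bw, axis=1)
        pixel_mask &= ~drop_px
        logger.warning("%d/%d blocks dropped (> %.0f%% holes)", int(dropped.sum()),
                       m * n, 100 * max_block_hole_fraction)
    trend = trend * pixel_mask[None, None]
    detrended = detrended * pixel_mask[None, None]
    return DecomposedVideo(
        trend=trend,
        detrended=detrended,
        channels=roi.channels,
        grid=grid,
        fps=roi.fps,
        timestamps=roi.timestamps.copy(),
        pixel_mask=pixel_mask,
        dropped_blocks=dropped,
        trends=trends,
        bit_depth=roi.bit_depth,
    )


def shift_reference(ref: SpO2Series, advance_s: float) -> SpO2Series:
    """Advance the fingertip reference by ``advance_s`` seconds.

    The facial signal leads the fingertip oximeter by ~20 s, so training labels
    are ``label(t) = ref(t + advance)``; times that have no shifted value simply
    yield no label.
    """
    if advance_s < 0:
        raise ValueError("advance must be >= 0")
    new_times = ref.times - advance_s
    keep = new_times >= -1e-9
    return SpO2Series(np.round(new_times[keep], 9), ref.values[keep])


def slice_observations(
    dec: DecomposedVideo,
    labels: SpO2Series | None,
    require_label: bool = True,
) -> list[Observation]:
    """Slice the decomposition into non-overlapping 1-s, 15-frame observations.

    Windows are aligned to whole seconds of the video time base; each
    concatenates the detrended channels then the trend channels.  The label is
    the 1 Hz reference value whose timestamp equals the window-start second; an
    incomplete final window and unlabeled windows are dropped (count logged).
    """
    if abs(dec.fps - 15.0) > 1e-9:
        raise ValueError("observation slicing assumes a 15 Hz frame rate")
    T = dec.n_frames
    n_windows = T // 15
    obs: list[Observation] = []
    n_unlabeled = 0
    for kw in range(n_windows):
        sl = slice(kw * 15, kw * 15 + 15)
        start_time = float(dec.timestamps[kw * 15])
        label = labels.at(start_time) if labels is not None else None
        if label is None and require_label:
            n_unlabeled += 1
            continue
        vol = np.concatenate([dec.detrended[:, sl], dec.trend[:, sl]], axis=0)
        obs.append(
            Observation(
                vol.astype(np.float32),
                None if label is None else int(round(label)),
                start_time,
                pixel_mask=dec.pixel_mask.copy(),
            )
        )
    if n_unlabeled:
        logger.info("dropped %d unlabeled 1-s windows", n_unlabeled)
    return obs


def select_channels(observations: Sequence[Observation], mode: str) -> list[Observation]:
    """Restrict observations to a modality subset: 'all', 'rgb' or 'nir'.

    Selection keeps the paired detrended+trend structure, e.g. 'nir' yields 4
    channels (detrended 780/940 then trend 780/940) through the identical
    downstream code path.
    """
    if mode == "all":
        return list(observations)
    picks = {"rgb": [0, 1, 2], "nir": [3, 4]}.get(mode)
    if picks is None:
        raise ValueError(f"unknown channel mode '{mode}'")
    C = len(CHANNEL_ORDER)
    idx = picks + [p + C for p in picks]
    return [
        Observation(o.volume[idx], o.label, o.start_time, o.pixel_mask)
        for o in observations
    ]
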
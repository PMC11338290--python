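"""Agreement evaluation between estimated and reference SpO2 series.

Implements the standard camera-oximetry evaluation stack: mean absolute error,
Pearson correlation, Bland–Altman bias and 95 % limits of agreement
(bias ± 1.96 × sample SD of the paired differences), and PERC — the percentage
of 1-s time points whose absolute error falls within a threshold.  Because the
facial signal leads a fingertip oximeter by roughly 20 s, evaluation first
aligns the reference by scanning integer-second shifts in a 20 ± 5 s window
and keeping the shift that maximises the Pearson correlation.

A classical ratio-of-ratios estimator over the detrended/trend decomposition is
included as a physics oracle: it needs no training and recovers SpO2 directly
from the AC/DC ratios of the red and NIR 940 nm channels, which makes it the
reference check that the registration → tracking → detrending chain preserves
the oximetry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import DecomposedVideo
from .series import SpO2Series

__all__ = [
    "EvalReport",
    "RREstimate",
    "mae",
    "pearson",
    "bias_loa",
    "perc_within",
    "align_reference",
    "bland_altman",
    "ratio_of_ratios_estimate",
    "evaluate_agreement",
]


def _check_aligned(est: SpO2Series, ref: SpO2Series, min_len: int = 1) -> None:
    if len(est) != len(ref):
        raise ValueError(f"series length mismatch: {len(est)} vs {len(ref)}")
    if len(est) < min_len:
        raise ValueError(f"need at least {min_len} aligned points")
    if not np.allclose(est.times, ref.times):
        raise ValueError("series timestamps are not aligned")


def mae(est: SpO2Series, ref: SpO2Series) -> float:
    """Mean absolute error in percentage points."""
    _check_aligned(est, ref, 1)
    return float(np.mean(np.abs(est.values.astype(float) - ref.values.astype(float))))


def pearson(est: SpO2Series, ref: SpO2Series) -> float:
    """Product-moment correlation; constant series are an explicit error."""
    _check_aligned(est, ref, 2)
    x = est.values.astype(float)
    y = ref.values.astype(float)
    sx = x - x.mean()
    sy = y - y.mean()
    nx = np.sqrt((sx**2).sum())
    ny = np.sqrt((sy**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined for a constant series")
    return float((sx * sy).sum() / (nx * ny))


def bias_loa(est: SpO2Series, ref: SpO2Series) -> tuple[float, float, float]:
    """Bland–Altman bias and 95 % limits of agreement.

    Differences are est - ref; the limits are bias ± 1.96 × sample (n-1) SD.
    """
    _check_aligned(est, ref, 2)
    diffs = est.values.astype(float) - ref.values.astype(float)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def perc_within(est: SpO2Series, ref: SpO2Series, thresholds=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10)):
    """PERC table: percentage of time points with |error| <= k for each k."""
    _check_aligned(est, ref, 1)
    err = np.abs(est.values.astype(float) - ref.values.astype(float))
    return {int(k): float(100.0 * np.mean(err <= k)) for k in thresholds}


def align_reference(
    est: SpO2Series,
    ref: SpO2Series,
    nominal_s: int = 20,
    half_window_s: int = 5,
    min_overlap: int = 10,
) -> tuple[int, SpO2Series, SpO2Series]:
    """Shift the reference within ``nominal ± half_window`` s to best match.

    Integer-second shifts are scanned at the reference's 1 Hz resolution; the
    shift maximising the Pearson correlation on the overlap wins, ties broken
    toward the nominal lag and then toward the smaller shift.  Returns
    ``(shift, est_aligned, ref_aligned)`` with identical time bases.
    """
    candidates = list(range(nominal_s - half_window_s, nominal_s + half_window_s + 1))
    results = []
    for s in candidates:
        shifted_times = np.round(ref.times - s, 9)
        common, ie, ir = np.intersect1d(np.round(est.times, 9), shifted_times,
                                        return_indices=True)
        if common.size < min_overlap:
            raise ValueError(f"insufficient overlap ({common.size}) at shift {s} s")
        x = est.values[ie].astype(float)
        y = ref.values[ir].astype(float)
        sx, sy = x - x.mean(), y - y.mean()
        denom = np.sqrt((sx**2).sum() * (sy**2).sum())
        rho = float((sx * sy).sum() / denom) if denom > 0 else -np.inf
        results.append((rho, -abs(s - nominal_s), -s, s, common, ie, ir))
    rho, _, _, s_best, common, ie, ir = max(results)
    est_al = SpO2Series(common, est.values[ie])
    ref_al = SpO2Series(common, ref.values[ir])
    return s_best, est_al, ref_al


def bland_altman(est: SpO2Series, ref: SpO2Series):
    """Per-point (mean, difference) table plus the bias/LoA reference lines."""
    _check_aligned(est, ref, 2)
    e = est.values.astype(float)
    r = ref.values.astype(float)
    means = (e + r) / 2.0
    diffs = e - r
    bias, lo, hi = bias_loa(est, ref)
    return means, diffs, (bias, lo, hi)


@dataclass
class EvalReport:
    """Agreement summary: MAE, Pearson rho, bias, 95 % LoA, PERC table."""

    mae: float
    pearson: float
    bias: float
    loa_low: float
    loa_high: float
    perc: dict[int, float]
    n: int
    alignment_shift_s: int | None = None

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("bias must lie inside the limits of agreement")

    def to_dict(self) -> dict:
        d = {
            "mae_percent": self.mae,
            "pearson_rho": None if np.isnan(self.pearson) else self.pearson,
            "bias_percent": self.bias,
            "loa_low_percent": self.loa_low,
            "loa_high_percent": self.loa_high,
            "perc": {str(k): v for k, v in self.perc.items()},
            "n": self.n,
        }
        if self.alignment_shift_s is not None:
            d["alignment_shift_s"] = self.alignment_shift_s
        return d


def evaluate_agreement(
    est: SpO2Series,
    ref: SpO2Series,
    align: bool = True,
    nominal_s: int = 20,
    half_window_s: int = 5,
) -> EvalReport:
    """Full agreement report, optionally after the 20 ± 5 s reference alignment."""
    shift = None
    if align:
        shift, est, ref = align_reference(est, ref, nominal_s, half_window_s)
    b, lo, hi = bias_loa(est, ref)
    try:
        rho = pearson(est, ref)
    except ValueError:
        rho = float("nan")  # constant series: undefined, reported explicitly
    return EvalReport(
        mae=mae(est, ref),
        pearson=rho,
        bias=b,
        loa_low=lo,
        loa_high=hi,
        perc=perc_within(est, ref),
        n=len(est),
        alignment_shift_s=shift,
    )


# ---------------------------------------------------------------------------
# classical ratio-of-ratios estimator (physics oracle)
# ---------------------------------------------------------------------------


@dataclass
class RREstimate:
    """Windowed ratio-of-ratios SpO2 estimates with validity flags."""

    times: np.ndarray  # window centres (s)
    values: np.ndarray  # estimated SpO2 (%)
    valid: np.ndarray  # per-window validity
    rr: np.ndarray  # raw ratio-of-ratios per window


def ratio_of_ratios_estimate(
    dec: DecomposedVideo,
    window_s: float = 10.0,
    A: float = 110.0,
    B: float = 25.0,
    red_channel: str = "r",
    nir_channel: str = "nir940",
) -> RREstimate:
    """Classical SpO2 estimation from the trend/detrended decomposition.

    Per window: AC_c is the standard deviation of the detrended spatial-mean
    signal, DC_c the mean of the trend spatial-mean; then
    ``RR = (AC_red / DC_red) / (AC_nir / DC_nir)`` and ``S = A - B * RR``.
    Windows with non-positive DC or zero NIR AC are flagged invalid.  The
    window should cover at least one cardiac cycle.
    """
    ci_r = dec.channels.index(red_channel)
    ci_n = dec.channels.index(nir_channel)
    mask = dec.pixel_mask
    if not mask.any():
        raise ValueError("decomposition has no usable pixels")
    m = mask.astype(float)
    wsum = m.sum()
    det = (dec.detrended[[ci_r, ci_n]] * m).sum(axis=(2, 3)) / wsum  # (2, T)
    trd = (dec.trend[[ci_r, ci_n]] * m).sum(axis=(2, 3)) / wsum
    wlen = int(round(window_s * dec.fps))
    if wlen < 2:
        raise ValueError("window too short")
    n_win = dec.n_frames // wlen
    times = np.empty(n_win)
    values = np.full(n_win, np.nan)
    valid = np.zeros(n_win, dtype=bool)
    rr = np.full(n_win, np.nan)
    for i in range(n_win):
        sl = slice(i * wlen, (i + 1) * wlen)
        times[i] = float(dec.timestamps[sl].mean())
        ac = det[:, sl].std(axis=1, ddof=1)
        dc = trd[:, sl].mean(axis=1)
        if dc[0] <= 0 or dc[1] <= 0 or ac[1] <= 1e-9 * max(abs(dc[1]), 1.0):
            continue
        rr[i] = (ac[0] / dc[0]) / (ac[1] / dc[1])
        values[i] = A - B * rr[i]
        valid[i] = True
    return RREstimate(times, values, valid, rr)
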
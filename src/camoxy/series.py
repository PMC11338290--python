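"""1 Hz SpO2 time series shared by the preprocessing, simulation and evaluation layers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpO2Series", "read_reference_csv", "write_reference_csv"]


@dataclass
class SpO2Series:
    """Integer-percent SpO2 values on a strictly increasing 1 Hz time base."""

    times: np.ndarray  # seconds
    values: np.ndarray  # integer percent

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.values = np.asarray(self.values).reshape(-1)
        if self.times.shape != self.values.shape:
            raise ValueError("times / values length mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        vals = np.asarray(self.values, dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100):
            raise ValueError("SpO2 values must lie in [0, 100]")

    def __len__(self) -> int:
        return self.times.size

    def at(self, t: float, tol: float = 1e-6) -> float | None:
        """Value whose timestamp equals ``t`` (within ``tol``), else None."""
        idx = np.flatnonzero(np.abs(self.times - t) <= tol)
        return float(self.values[idx[0]]) if idx.size else None


def read_reference_csv(path: str | Path) -> SpO2Series:
    df = pd.read_csv(path)
    for col in ("time_s", "spo2_percent"):
        if col not in df.columns:
            raise ValueError(f"reference CSV missing column '{col}'")
    return SpO2Series(df["time_s"].to_numpy(), df["spo2_percent"].to_numpy())


def write_reference_csv(path: str | Path, series: SpO2Series) -> None:
    pd.DataFrame({"time_s": series.times, "spo2_percent": series.values}).to_csv(
        path, index=False
    )
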
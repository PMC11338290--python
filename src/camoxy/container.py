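"""HDF5 recording container for synchronized multimodal video.

One file holds the five registered intensity channels (``rgb/r``, ``rgb/g``,
``rgb/b``, ``nir780``, ``nir940``) and the stereo ``disparity`` stack, all
``(T, H, W)`` on a shared 15 Hz time base, plus per-frame indexed 2D facial
landmarks, the camera calibration (embedded JSON), the 1 Hz reference SpO2
series, and an optional ground-truth group written by the simulator.  A format
version attribute guards against silently reading an incompatible layout.

The reference series may also live in a sidecar CSV (``time_s,
spo2_percent``); when both are present the embedded copy wins with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .geometry import calibration_from_dict
from .series import SpO2Series, read_reference_csv

__all__ = ["RecordingContainer", "write_container", "read_container", "FORMAT_VERSION"]

FORMAT_VERSION = "1"
CHANNEL_KEYS = ("r", "g", "b", "nir780", "nir940")


@dataclass
class RecordingContainer:
    """In-memory multimodal recording."""

    channels: dict[str, np.ndarray]  # each (T, H, W)
    disparity: np.ndarray  # (T, H, W)
    timestamps: np.ndarray  # (T,) seconds
    landmark_indices: np.ndarray  # (L,) face-mesh indices
    landmarks2d: np.ndarray  # (T, L, 2) px on the reference modality
    calibration: dict
    reference: SpO2Series | None = None
    fps: float = 15.0
    bit_depth: int = 8
    ground_truth: dict[str, np.ndarray] | None = None
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        T = self.timestamps.size
        for name, stack in self.channels.items():
            if stack.shape[0] != T:
                raise ValueError(f"channel '{name}' frame count != timestamps")
        if self.disparity.shape[0] != T:
            raise ValueError("disparity frame count != timestamps")
        if self.landmarks2d.shape[0] != T:
            raise ValueError("landmarks frame count != timestamps")
        if self.landmark_indices.size > 468:
            raise ValueError("at most 468 landmarks are supported")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    @property
    def image_size(self) -> tuple[int, int]:
        h, w = self.disparity.shape[1:]
        return (w, h)

    def cameras(self):
        """Decode the embedded calibration: (cameras, rig, reference name)."""
        return calibration_from_dict(self.calibration)


def write_container(path: str | Path, container: RecordingContainer) -> None:
    """Write the container losslessly to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = container.format_version
        f.attrs["fps"] = container.fps
        f.attrs["bit_depth"] = container.bit_depth
        for key in ("r", "g", "b"):
            f.create_dataset(f"rgb/{key}", data=container.channels[key])
        for key in ("nir780", "nir940"):
            f.create_dataset(key, data=container.channels[key])
        f.create_dataset("disparity", data=container.disparity)
        f.create_dataset("timestamps", data=container.timestamps)
        f.create_dataset("landmarks/indices", data=container.landmark_indices)
        f.create_dataset("landmarks/coords", data=container.landmarks2d)
        f.create_dataset("calibration_json", data=json.dumps(container.calibration))
        if container.reference is not None:
            f.create_dataset("reference/time_s", data=container.reference.times)
            f.create_dataset("reference/spo2", data=container.reference.values)
        if container.ground_truth:
            for key, arr in container.ground_truth.items():
                f.create_dataset(f"ground_truth/{key}", data=arr)


def read_container(
    path: str | Path,
    required_channels: tuple[str, ...] = CHANNEL_KEYS,
    reference_csv: str | Path | None = None,
) -> RecordingContainer:
    """Read a recording; missing required groups and unknown versions are errors."""
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("format_version", ""))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"container format version '{version}' not supported "
                f"(expected '{FORMAT_VERSION}')"
            )
        channels: dict[str, np.ndarray] = {}
        for key in required_channels:
            h5key = f"rgb/{key}" if key in ("r", "g", "b") else key
            if h5key not in f:
                raise ValueError(f"container missing required group '{key}'")
            channels[key] = f[h5key][...]
        for key in CHANNEL_KEYS:
            h5key = f"rgb/{key}" if key in ("r", "g", "b") else key
            if key not in channels and h5key in f:
                channels[key] = f[h5key][...]
        for name in ("disparity", "timestamps", "landmarks/indices", "landmarks/coords",
                     "calibration_json"):
            if name not in f:
                raise ValueError(f"container missing required group '{name}'")
        reference = None
        if "reference/time_s" in f:
            reference = SpO2Series(f["reference/time_s"][...], f["reference/spo2"][...])
        if reference_csv is not None:
            csv_ref = read_reference_csv(reference_csv)
            if reference is not None:
                warnings.warn(
                    "both embedded and CSV reference present: embedded copy wins",
                    stacklevel=2,
                )
            else:
                reference = csv_ref
        ground_truth = None
        if "ground_truth" in f:
            ground_truth = {k: f[f"ground_truth/{k}"][...] for k in f["ground_truth"]}
        return RecordingContainer(
            channels=channels,
            disparity=f["disparity"][...],
            timestamps=f["timestamps"][...],
            landmark_indices=f["landmarks/indices"][...],
            landmarks2d=f["landmarks/coords"][...],
            calibration=json.loads(f["calibration_json"][()].decode()
                                   if isinstance(f["calibration_json"][()], bytes)
                                   else str(f["calibration_json"][()])),
            reference=reference,
            fps=float(f.attrs["fps"]),
            bit_depth=int(f.attrs["bit_depth"]),
            ground_truth=ground_truth,
            format_version=version,
        )
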
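"""Shared fixtures: small synthetic recordings and camera rigs.

All fixtures are deterministic (fixed seeds) and sized so the whole unit suite
runs in a couple of minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from camoxy.container import RecordingContainer
from camoxy.geometry import CameraModel, StereoRig, calibration_to_dict
from camoxy.series import SpO2Series
from camoxy.simulate import SimConfig, simulate_recording


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """4 s recording with default motion, noise and texture."""
    cfg = SimConfig(duration_s=4.0, breath_cycles=0, seed=42)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def flat_noiseless_recording():
    """Flat surface, zero noise, exact-landmark recording for tight oracles."""
    cfg = SimConfig(
        duration_s=4.0,
        breath_cycles=0,
        curvature_radius_m=np.inf,
        noise_sigma=0.0,
        landmark_noise_px=0.0,
        seed=7,
    )
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def static_pulse_recording():
    """Static pose, zero noise, one desaturation cycle — physics-oracle scene."""
    cfg = SimConfig(
        duration_s=60.0,
        breath_cycles=1,
        breath_nadirs=(85.0,),
        breath_start_s=20.0,
        noise_sigma=0.0,
        pose_amplitude_deg=0.0,
        pose_amplitude_mm=0.0,
        landmark_noise_px=0.0,
        seed=5,
    )
    return simulate_recording(cfg)


def make_flat_container(T: int = 30, size: tuple[int, int] = (32, 28),
                        gradient: bool = True) -> RecordingContainer:
    """Hand-built static container: constant-in-time images, flat geometry.

    The reference camera is the rectified camera (identity extrinsics), the
    surface is the plane z = 1 m, and landmarks sit on a fixed pixel grid, so
    every geometric quantity has a closed form.
    """
    w, h = size
    f = 100.0
    K = np.array([[f, 0, (w - 1) / 2], [0, f, (h - 1) / 2], [0, 0, 1.0]])
    cam = CameraModel(K, np.eye(3), np.zeros(3), (w, h), name="rgb")
    cameras = {
        "rgb": cam,
        "nir780": CameraModel(K, np.eye(3), np.zeros(3), (w, h), name="nir780"),
        "nir940": CameraModel(K, np.eye(3), np.zeros(3), (w, h), name="nir940"),
    }
    rig = StereoRig(f, 0.1, np.eye(3), cam)
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    frame = 50.0 + (2.0 * uu + 3.0 * vv if gradient else 0.0)
    disparity = np.full((h, w), f * 0.1 / 1.0)  # plane at z = 1 m
    channels = {
        c: np.repeat(frame[None] + 10 * i, T, axis=0).astype(np.float32)
        for i, c in enumerate(("r", "g", "b", "nir780", "nir940"))
    }
    lm_idx = np.arange(12)
    lm_uv = np.stack(np.meshgrid(np.linspace(6, w - 7, 4), np.linspace(6, h - 7, 3)),
                     axis=-1).reshape(-1, 2)
    ref = SpO2Series(np.arange(T // 15 + 1, dtype=float), np.full(T // 15 + 1, 97))
    return RecordingContainer(
        channels=channels,
        disparity=np.repeat(disparity[None], T, axis=0).astype(np.float32),
        timestamps=np.arange(T) / 15.0,
        landmark_indices=lm_idx,
        landmarks2d=np.repeat(lm_uv[None], T, axis=0),
        calibration=calibration_to_dict(cameras, rig, "rgb"),
        reference=ref,
        fps=15.0,
        bit_depth=8,
    )


@pytest.fixture
def flat_container() -> RecordingContainer:
    return make_flat_container()
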
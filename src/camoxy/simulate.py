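"""Synthetic multimodal facial-video generator with known SpO2 ground truth.

Emulates the acquisition protocol of a breath-holding study in front of a
calibrated VIS-NIR multi-camera rig, producing a complete recording container
(R/G/B, NIR 780, NIR 940 frame stacks at 15 Hz, disparity maps of the rectified
stereo pair, indexed 2D facial landmarks, calibration, and a lagged 1 Hz
fingertip-style reference) together with a full ground-truth ledger.

The scene is a curved, textured forehead-like surface — a paraboloid patch —
moved rigidly by a smooth 6-DoF pose trajectory.  Images are rendered by exact
per-pixel ray/paraboloid intersection (closed-form quadratic), so every
geometric quantity (disparity, landmark positions, ROI surface points) has an
analytic oracle.  Surface radiance in channel ``c`` is

    I_c(x, y, t) = G_c(t) * DC_c(x, y) * (1 - alpha_c(S(t)) * p(t)) + noise

with ``p(t)`` a unit-amplitude cardiac waveform, ``G_c`` a slow illumination
drift, and modulation depths tied to SpO2 through the classic linear
ratio-of-ratios calibration ``S = A - B * RR``: the NIR 940 nm depth is the
constant ``a0`` and the red depth is ``a0 * RR(S(t))``, so the AC/DC ratio of
ratios computed from the rendered video inverts exactly to ``S``.  The G, B and
780 nm depths interpolate between the red and 940 nm endpoints by wavelength.

The exported reference series is the facial SpO2 trace delayed by the
configured lag (~20 s), mimicking the circulatory delay between face and
fingertip.  All randomness derives from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .container import RecordingContainer
from .geometry import CameraModel, StereoRig, calibration_to_dict
from .series import SpO2Series

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SurfaceModel",
    "breath_hold_trace",
    "spo2_to_rr",
    "rr_to_spo2",
    "simulate_recording",
    "default_cameras",
    "FOREHEAD_LANDMARKS",
]

#: face-mesh indices conventionally covering the forehead (subset of 0..467)
FOREHEAD_LANDMARKS = (
    10, 109, 338, 67, 297, 103, 332, 54, 284, 21, 251, 68,
    298, 104, 333, 69, 299, 108, 337, 151, 9, 66, 296, 107,
)

_WAVELENGTH_NM = {"r": 660.0, "g": 520.0, "b": 460.0, "nir780": 780.0, "nir940": 940.0}
_BASE_REFLECTANCE = {"r": 0.55, "g": 0.45, "b": 0.35, "nir780": 0.60, "nir940": 0.60}


# ---------------------------------------------------------------------------
# SpO2 <-> ratio-of-ratios calibration
# ---------------------------------------------------------------------------


def spo2_to_rr(S, A: float = 110.0, B: float = 25.0):
    """Invert the linear pulse-oximetry calibration: RR = (A - S) / B."""
    if B == 0:
        raise ValueError("calibration slope B must be nonzero")
    return (A - np.asarray(S, dtype=float)) / B


def rr_to_spo2(RR, A: float = 110.0, B: float = 25.0):
    """Linear pulse-oximetry calibration S = A - B * RR."""
    if B == 0:
        raise ValueError("calibration slope B must be nonzero")
    return A - B * np.asarray(RR, dtype=float)


# ---------------------------------------------------------------------------
# breath-hold SpO2 trace
# ---------------------------------------------------------------------------


def breath_hold_trace(
    duration_s: float = 240.0,
    n_cycles: int = 3,
    baseline: float = 98.0,
    nadirs: tuple[float, ...] = (88.0, 84.0, 80.0),
    down_slope: float = 0.7,
    up_slope: float = 2.0,
    hold_s: float = 5.0,
    start_s: float = 40.0,
) -> SpO2Series:
    """Piecewise breath-hold/desaturation trace at 1 Hz, integer percent.

    Each cycle: plateau at ``baseline``, ramp down at ``down_slope`` %/s to its
    nadir, hold ``hold_s`` seconds, recover at ``up_slope`` %/s.  Cycles start
    at ``start_s`` and are spread evenly over the remaining duration.  Slopes
    that do not fit in a cycle are an error.
    """
    if n_cycles > 0:
        for nad in nadirs:
            if not (70.0 <= nad < baseline):
                raise ValueError(f"nadir {nad} outside [70, baseline)")
    times = np.arange(int(np.floor(duration_s)), dtype=float)
    values = np.full(times.size, baseline)
    if n_cycles > 0:
        period = (duration_s - start_s) / n_cycles
        for i in range(n_cycles):
            nad = nadirs[i % len(nadirs)]
            t_down = (baseline - nad) / down_slope
            t_up = (baseline - nad) / up_slope
            if t_down + hold_s + t_up > period:
                raise ValueError("infeasible slopes: cycle does not fit the duration")
            t0 = start_s + i * period
            seg = times - t0
            in_down = (seg >= 0) & (seg < t_down)
            in_hold = (seg >= t_down) & (seg < t_down + hold_s)
            in_up = (seg >= t_down + hold_s) & (seg < t_down + hold_s + t_up)
            values[in_down] = baseline - down_slope * seg[in_down]
            values[in_hold] = nad
            values[in_up] = nad + up_slope * (seg[in_up] - t_down - hold_s)
    lo = min(nadirs) if n_cycles > 0 else baseline
    values = np.clip(np.round(values), lo, baseline)
    return SpO2Series(times, values.astype(int))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions of the synthetic recording.

    Temporal/protocol constants (15 Hz, ~4 min, three breath-hold cycles
    spanning 80–98 %, ~20 s fingertip lag) mirror the breath-holding protocol;
    frame geometry is a scaled-down rig (small images, short focal) so full
    recordings fit comfortably in memory.
    """

    duration_s: float = 240.0
    fps: float = 15.0
    image_size: tuple[int, int] = (96, 80)  # (width, height)
    focal_px: float = 576.0
    baseline_m: float = 0.05
    surface_distance_m: float = 1.5
    surface_extent_m: tuple[float, float] = (0.20, 0.16)
    curvature_radius_m: float = 0.15
    # radiance model
    base_reflectance: Mapping[str, float] = field(default_factory=lambda: dict(_BASE_REFLECTANCE))
    illumination: float = 0.9  # full-scale fraction at reflectance 1.0
    texture_contrast: float = 0.10  # rms of the smooth reflectance field
    n_texture_waves: int = 6
    n_markers: int = 4
    marker_amplitude: float = 0.30
    marker_sigma_m: float = 0.006
    calib_A: float = 110.0
    calib_B: float = 25.0
    a0: float = 0.05  # NIR 940 nm AC/DC modulation depth
    heart_rate_bpm: float = 70.0
    harmonic2: float = 0.3
    drift_amplitude: float = 0.02
    drift_period_s: float = 120.0
    noise_sigma: float = 1.0  # gray levels
    bit_depth: int = 8
    # motion
    pose_amplitude_deg: float = 2.0
    pose_amplitude_mm: float = 3.0
    pose_freq_hz: float = 0.08
    landmark_noise_px: float = 0.2
    n_landmarks: int = 24
    roi_size: tuple[int, int] = (40, 40)  # (h, w) px on the reference image
    # reference protocol
    reference_lag_s: float = 20.0
    breath_baseline: float = 98.0
    breath_nadirs: tuple[float, ...] = (88.0, 84.0, 80.0)
    breath_cycles: int = 3
    breath_down_slope: float = 0.7
    breath_up_slope: float = 2.0
    breath_hold_s: float = 5.0
    breath_start_s: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.fps - 15.0) > 1e-9:
            raise ValueError("the rig's 2D cameras run at 15 Hz")
        if self.duration_s < 2:
            raise ValueError("duration must be >= 2 s")
        if not 0 < self.a0 < 0.2:
            raise ValueError("a0 must lie in (0, 0.2)")


def _rot(axis: int, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == 0:
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    elif axis == 1:
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    else:
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    return R


def default_cameras(cfg: SimConfig) -> tuple[dict[str, CameraModel], StereoRig, str]:
    """Calibrated camera set: RGB reference plus offset NIR 780/940 cameras."""
    w, h = cfg.image_size
    K = np.array([[cfg.focal_px, 0.0, (w - 1) / 2], [0.0, cfg.focal_px, (h - 1) / 2], [0, 0, 1.0]])

    def cam(name, R, centre):
        return CameraModel(K, R, -R @ np.asarray(centre, float), (w, h), name=name)

    rect_R = _rot(1, np.deg2rad(1.5))

    def lookat_cam(name, centre_world) -> CameraModel:
        """Off-axis camera boresighted at the surface centre.

        ``centre_world`` is the camera position in the rectified (world) frame;
        the stored extrinsics are w.r.t. the unrectified reference frame, i.e.
        R_c = A @ R_rect with A the world-frame look-at rotation."""
        o = np.asarray(centre_world, float)
        v = np.array([0.0, 0.0, cfg.surface_distance_m]) - o
        ay = -np.arctan2(v[0], v[2])
        v2 = _rot(1, ay) @ v
        ax = np.arctan2(v2[1], v2[2])
        A = _rot(0, ax) @ _rot(1, ay)
        return CameraModel(K, A @ rect_R, -A @ o, (w, h), name=name)

    # The colour camera is mounted as the rectified stereo reference (its
    # extrinsics equal R_rect), so the organised cloud, the landmarks and the
    # ROI all share one pixel grid — the registered-to-reference layout the
    # downstream pipeline assumes.  The NIR cameras sit off-axis and are
    # boresighted at the surface centre.
    cameras = {
        "rgb": cam("rgb", rect_R, (0.0, 0.0, 0.0)),
        "nir780": lookat_cam("nir780", (0.03, 0.005, 0.0)),
        "nir940": lookat_cam("nir940", (-0.03, 0.01, 0.0)),
    }
    rig = StereoRig(cfg.focal_px, cfg.baseline_m, rect_R, cameras["rgb"])
    return cameras, rig, "rgb"


# ---------------------------------------------------------------------------
# surface radiance model
# ---------------------------------------------------------------------------


@dataclass
class SurfaceModel:
    """Analytic reflectance/pulse model of the synthetic forehead surface."""

    cfg: SimConfig
    wave_k: np.ndarray  # (n_waves, 2) spatial frequencies (rad/m)
    wave_phase: np.ndarray
    wave_amp: np.ndarray
    marker_centres: np.ndarray  # (n_markers, 2) m
    marker_amp: np.ndarray
    drift_phase: dict[str, float]
    pulse_norm: float

    def texture(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        t = np.zeros_like(a)
        for (kx, ky), ph, amp in zip(self.wave_k, self.wave_phase, self.wave_amp):
            t += amp * np.cos(kx * a + ky * b + ph)
        s2 = 2 * self.cfg.marker_sigma_m**2
        for (ma, mb), amp in zip(self.marker_centres, self.marker_amp):
            t += amp * np.exp(-((a - ma) ** 2 + (b - mb) ** 2) / s2)
        return np.maximum(1.0 + t, 0.2)

    def dc(self, a: np.ndarray, b: np.ndarray, channel: str) -> np.ndarray:
        """Static gray-level field G-independent part: full_scale * illum * refl."""
        full = 2**self.cfg.bit_depth - 1
        return full * self.cfg.illumination * self.cfg.base_reflectance[channel] * self.texture(a, b)

    def alpha(self, channel: str, S) -> np.ndarray:
        """SpO2-dependent AC/DC modulation depth for one channel."""
        rr = spo2_to_rr(S, self.cfg.calib_A, self.cfg.calib_B)
        wl = _WAVELENGTH_NM[channel]
        wgt = (940.0 - wl) / (940.0 - 660.0)
        return self.cfg.a0 * (1.0 + (rr - 1.0) * wgt)

    def pulse(self, t) -> np.ndarray:
        f = self.cfg.heart_rate_bpm / 60.0
        t = np.asarray(t, dtype=float)
        raw = np.sin(2 * np.pi * f * t) + self.cfg.harmonic2 * np.sin(4 * np.pi * f * t + 0.9)
        return raw / self.pulse_norm

    def gain(self, channel: str, t) -> np.ndarray:
        return 1.0 + self.cfg.drift_amplitude * np.sin(
            2 * np.pi * np.asarray(t, dtype=float) / self.cfg.drift_period_s
            + self.drift_phase[channel]
        )

    def radiance(self, a, b, t, S, channel: str) -> np.ndarray:
        """Noise-free rendered gray value at material point (a, b), time t."""
        return self.gain(channel, t) * self.dc(a, b, channel) * (
            1.0 - self.alpha(channel, S) * self.pulse(t)
        )


def _build_surface(cfg: SimConfig, rng: np.random.Generator) -> SurfaceModel:
    nw = cfg.n_texture_waves
    freq = rng.uniform(20.0, 80.0, size=nw)  # cycles/m -> cm-scale texture
    theta = rng.uniform(0, 2 * np.pi, size=nw)
    wave_k = 2 * np.pi * freq[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    amp = rng.uniform(0.5, 1.0, size=nw)
    if nw:
        amp *= cfg.texture_contrast / np.sqrt(0.5 * np.sum(amp**2))
    ex, ey = cfg.surface_extent_m
    centres = rng.uniform(-0.35, 0.35, size=(cfg.n_markers, 2)) * np.array([ex, ey])
    mamp = cfg.marker_amplitude * rng.choice([-1.0, 1.0], size=cfg.n_markers)
    drift_phase = {c: float(rng.uniform(0, 2 * np.pi)) for c in _WAVELENGTH_NM}
    # normalise the cardiac waveform to unit amplitude
    tt = np.linspace(0, 60.0 / cfg.heart_rate_bpm, 2001)
    raw = np.sin(2 * np.pi * cfg.heart_rate_bpm / 60.0 * tt) + cfg.harmonic2 * np.sin(
        4 * np.pi * cfg.heart_rate_bpm / 60.0 * tt + 0.9
    )
    return SurfaceModel(cfg, wave_k, rng.uniform(0, 2 * np.pi, nw), amp, centres, mamp,
                        drift_phase, float(np.max(np.abs(raw))))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Ground-truth ledger of one synthetic recording."""

    rotations: np.ndarray  # (T, 3, 3) frame-1 -> frame-k world transforms
    translations: np.ndarray  # (T, 3)
    facial_trace: SpO2Series  # 1 Hz, integer %
    pulse: np.ndarray  # (T,) unit-amplitude cardiac waveform at frame times
    landmarks3d: np.ndarray  # (T, L, 3) world coordinates
    landmarks2d: np.ndarray  # (T, L, 2) noise-free reference-image projections
    alphas: dict[str, np.ndarray]  # per-channel modulation depth at frame times
    reference_lag_s: float
    clip_fraction: float
    roi_rect: tuple[int, int, int, int]
    surface: SurfaceModel
    spo2_at_frames: np.ndarray  # (T,) interpolated SpO2 used for rendering


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------


def _pose(cfg: SimConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth 6-DoF trajectory, identity at t=0: (T,3,3) rotations, (T,3) m."""
    amp = np.deg2rad(cfg.pose_amplitude_deg)
    f = cfg.pose_freq_hz
    ax = amp * np.sin(2 * np.pi * f * t)
    ay = amp * np.sin(2 * np.pi * 1.3 * f * t)
    az = 0.5 * amp * np.sin(2 * np.pi * 0.7 * f * t)
    R = np.einsum("tij,tjk->tik",
                  np.einsum("tij,tjk->tik", _rot_batch(2, az), _rot_batch(1, ay)),
                  _rot_batch(0, ax))
    amm = cfg.pose_amplitude_mm * 1e-3
    tr = np.stack([
        amm * np.sin(2 * np.pi * 0.9 * f * t),
        amm * np.sin(2 * np.pi * 1.1 * f * t),
        amm * np.sin(2 * np.pi * 0.6 * f * t),
    ], axis=1)
    return R, tr


def _rot_batch(axis: int, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    T = angles.size
    R = np.zeros((T, 3, 3))
    if axis == 0:
        R[:, 0, 0] = 1
        R[:, 1, 1], R[:, 1, 2], R[:, 2, 1], R[:, 2, 2] = c, -s, s, c
    elif axis == 1:
        R[:, 1, 1] = 1
        R[:, 0, 0], R[:, 0, 2], R[:, 2, 0], R[:, 2, 2] = c, s, -s, c
    else:
        R[:, 2, 2] = 1
        R[:, 0, 0], R[:, 0, 1], R[:, 1, 0], R[:, 1, 1] = c, -s, s, c
    return R


def _ray_surface(o: np.ndarray, d: np.ndarray, Rc: float):
    """Intersect rays (origin ``o`` (3,), directions ``d`` (N,3)) with the local
    paraboloid z = (x^2 + y^2) / (2 Rc).  Returns (lam, hit).

    ``Rc = inf`` degenerates to the plane z = 0 (handy for tests that need
    bilinear sampling of the cloud to be exact)."""
    if np.isinf(Rc):
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = -o[2] / d[:, 2]
        hit = np.isfinite(lam) & (lam > 0)
        return np.where(hit, lam, np.nan), hit
    A = d[:, 0] ** 2 + d[:, 1] ** 2
    B = 2 * (o[0] * d[:, 0] + o[1] * d[:, 1]) - 2 * Rc * d[:, 2]
    C = o[0] ** 2 + o[1] ** 2 - 2 * Rc * o[2]
    disc = B * B - 4 * A * C
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    q = -0.5 * (B + np.sign(np.where(B == 0, 1.0, B)) * sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(A > 1e-14, q / np.where(A > 1e-14, A, 1.0), np.inf)
        r2 = np.where(np.abs(q) > 1e-300, C / q, np.inf)
    lam = np.where((r1 > 0) & ((r1 < r2) | (r2 <= 0)), r1, r2)
    hit &= lam > 0
    return np.where(hit, lam, np.nan), hit


def simulate_recording(cfg: SimConfig) -> tuple[RecordingContainer, GroundTruth]:
    """Render one complete synthetic multimodal recording plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    surface = _build_surface(cfg, rng)
    cameras, rig, ref_name = default_cameras(cfg)
    w, h = cfg.image_size
    T = int(round(cfg.duration_s * cfg.fps))
    times = np.arange(T) / cfg.fps
    full = float(2**cfg.bit_depth - 1)

    trace = breath_hold_trace(cfg.duration_s, cfg.breath_cycles, cfg.breath_baseline,
                              cfg.breath_nadirs, cfg.breath_down_slope, cfg.breath_up_slope,
                              cfg.breath_hold_s, cfg.breath_start_s)
    S_frames = np.interp(times, trace.times, trace.values.astype(float))
    pulse = surface.pulse(times)
    alphas = {c: surface.alpha(c, S_frames) for c in _WAVELENGTH_NM}
    gains = {c: surface.gain(c, times) for c in _WAVELENGTH_NM}

    R_pose, t_pose = _pose(cfg, times)
    c0 = np.array([0.0, 0.0, cfg.surface_distance_m])
    Rc = cfg.curvature_radius_m
    ex, ey = cfg.surface_extent_m

    # landmark material points, clustered on the central part of the surface
    lm_local2 = rng.uniform(-0.3, 0.3, size=(cfg.n_landmarks, 2)) * np.array([ex, ey])
    lm_local = np.column_stack([lm_local2, (lm_local2**2).sum(axis=1) / (2 * Rc)])
    lm_indices = np.array(FOREHEAD_LANDMARKS[: cfg.n_landmarks])
    if cfg.n_landmarks > len(FOREHEAD_LANDMARKS):
        extra = [i for i in range(468) if i not in FOREHEAD_LANDMARKS]
        lm_indices = np.concatenate([
            np.array(FOREHEAD_LANDMARKS),
            np.array(extra[: cfg.n_landmarks - len(FOREHEAD_LANDMARKS)]),
        ])

    # per-camera constant ray directions in their own (unrect-ref) frame
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pix = np.stack([uu.ravel(), vv.ravel(), np.ones(w * h)], axis=1)
    rect_R = rig.rectification_rotation
    cam_rays = {}
    cam_origins = {}
    for name, cam in cameras.items():
        Kinv = np.linalg.inv(cam.intrinsics)
        d_ref = (pix @ Kinv.T) @ cam.rotation  # rows: R_c^T K^-1 pix
        cam_rays[name] = d_ref @ rect_R.T  # world (= rectified) frame
        cam_origins[name] = rect_R @ (-cam.rotation.T @ cam.translation)
    # rectified reference camera used for the disparity maps
    Kinv = np.linalg.inv(cameras[ref_name].intrinsics)
    disp_rays = pix @ Kinv.T  # world frame directly
    disp_origin = np.zeros(3)

    channels = {c: np.empty((T, h, w), dtype=np.float32) for c in _WAVELENGTH_NM}
    disparity = np.empty((T, h, w), dtype=np.float32)
    lm2d = np.empty((T, cfg.n_landmarks, 2))
    lm2d_clean = np.empty_like(lm2d)
    lm3d = np.empty((T, cfg.n_landmarks, 3))
    n_clipped = 0
    n_rendered = 0

    cam_channels = {"rgb": ["r", "g", "b"], "nir780": ["nir780"], "nir940": ["nir940"]}
    K_ref = cameras[ref_name].intrinsics

    for k in range(T):
        Rk = R_pose[k]
        tk = t_pose[k]
        shift = c0 + tk
        for cam_name, chans in cam_channels.items():
            o_l = Rk.T @ (cam_origins[cam_name] - shift)
            d_l = cam_rays[cam_name] @ Rk  # rows: Rk^T d
            lam, hitm = _ray_surface(o_l, d_l, Rc)
            pt = o_l[None, :] + lam[:, None] * d_l
            inside = hitm & (np.abs(pt[:, 0]) <= ex / 2) & (np.abs(pt[:, 1]) <= ey / 2)
            a = np.where(inside, pt[:, 0], 0.0)
            b = np.where(inside, pt[:, 1], 0.0)
            tex = surface.texture(a, b)
            for ch in chans:
                base = full * cfg.illumination * cfg.base_reflectance[ch]
                img = gains[ch][k] * base * tex * (1.0 - alphas[ch][k] * pulse[k])
                img = np.where(inside, img, 0.0)
                if cfg.noise_sigma > 0:
                    img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
                clipped = (img < 0) | (img > full)
                n_clipped += int(clipped[inside].sum())
                n_rendered += int(inside.sum())
                channels[ch][k] = np.clip(img, 0.0, full).reshape(h, w).astype(np.float32)
        # disparity of the rectified pair
        o_l = Rk.T @ (disp_origin - shift)
        d_l = disp_rays @ Rk
        lam, hitm = _ray_surface(o_l, d_l, Rc)
        pt = o_l[None, :] + lam[:, None] * d_l
        inside = hitm & (np.abs(pt[:, 0]) <= ex / 2) & (np.abs(pt[:, 1]) <= ey / 2)
        z = lam  # rays have unit z in the rectified frame
        disp = np.where(inside & (z > 0), rig.rectified_focal * rig.baseline / np.where(z > 0, z, 1.0), 0.0)
        disparity[k] = disp.reshape(h, w).astype(np.float32)
        # landmarks
        wpts = lm_local @ Rk.T + shift
        lm3d[k] = wpts
        cam = cameras[ref_name]
        p_cam = wpts @ (cam.rotation @ rect_R.T).T + cam.translation
        hom = p_cam @ K_ref.T
        lm2d_clean[k] = hom[:, :2] / hom[:, 2:3]
        lm2d[k] = lm2d_clean[k]
        if cfg.landmark_noise_px > 0:
            lm2d[k] = lm2d[k] + rng.normal(0, cfg.landmark_noise_px, size=lm2d[k].shape)

    if n_rendered == 0:
        raise ValueError("surface outside all camera frusta")
    clip_fraction = n_clipped / max(n_rendered, 1)

    # ROI rect centred on the frame-1 projection of the surface centre
    centre_px = K_ref @ (cameras[ref_name].rotation @ rect_R.T @ c0 + cameras[ref_name].translation)
    cu, cv = centre_px[0] / centre_px[2], centre_px[1] / centre_px[2]
    rh, rw = cfg.roi_size
    roi_rect = (int(round(cu)) - rw // 2, int(round(cv)) - rh // 2, rh, rw)

    # fingertip-style reference: facial trace delayed by the configured lag
    lag = int(round(cfg.reference_lag_s))
    ref_vals = np.empty(trace.values.size, dtype=int)
    for i, t in enumerate(trace.times):
        src = int(t) - lag
        ref_vals[i] = trace.values[src] if src >= 0 else trace.values[0]
    reference = SpO2Series(trace.times.copy(), ref_vals)

    # pose ground truth as frame-1 -> frame-k world transforms (frame 1 identity)
    gt_R = R_pose.copy()
    gt_t = np.stack([c0 + t_pose[k] - R_pose[k] @ c0 for k in range(T)])

    container = RecordingContainer(
        channels=channels,
        disparity=disparity,
        timestamps=times,
        landmark_indices=lm_indices,
        landmarks2d=lm2d,
        calibration=calibration_to_dict(cameras, rig, ref_name),
        reference=reference,
        fps=cfg.fps,
        bit_depth=cfg.bit_depth,
        ground_truth={
            "rotations": gt_R,
            "translations": gt_t,
            "facial_trace_times": trace.times,
            "facial_trace_values": trace.values.astype(float),
            "reference_lag_s": np.array([cfg.reference_lag_s]),
            "spo2_at_frames": S_frames,
        },
    )
    gt = GroundTruth(
        rotations=gt_R,
        translations=gt_t,
        facial_trace=trace,
        pulse=pulse,
        landmarks3d=lm3d,
        landmarks2d=lm2d_clean,
        alphas=alphas,
        reference_lag_s=cfg.reference_lag_s,
        clip_fraction=clip_fraction,
        roi_rect=roi_rect,
        surface=surface,
        spo2_at_frames=S_frames,
    )
    return container, gt
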
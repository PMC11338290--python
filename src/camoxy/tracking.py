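"""3D ROI tracking from facial landmarks.

The head is treated as a rigid body: a face-mesh detector provides up to 468
indexed 2D landmarks per frame on the reference modality, these are lifted into
the registered point cloud, and the 6-DoF rigid transform from the first frame's
landmark set ``P1`` to frame ``k``'s set ``Pk``

    (R_k, t_k) = argmin_{R,t} sum_i || R p_1i + t - p_ki ||^2

is solved in closed form (SVD of the centred cross-covariance, Kabsch/Umeyama,
with the determinant-sign correction so det(R) = +1).  The forehead ROI grid
defined on frame 1 is then carried to every frame, projected into each modality
and sampled bilinearly to yield fixed-size per-channel ROI crops.  Tracking
quality is scored by windowed SSIM of each crop against the frame-1 crop.

Frames are always matched to frame 1 (never chained) to avoid drift; landmark
correspondence is by mesh index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import CameraModel, PixelCoords, PointCloud, ROI3D, project_points, sample_bilinear

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "RoiTrack",
    "lift_landmarks",
    "estimate_rigid_transform",
    "track_roi",
    "crop_roi_video",
    "anonymize",
    "tracking_ssim",
    "ssim_uniform",
    "CHANNEL_CAMERA",
]

logger = logging.getLogger(__name__)

#: which calibrated camera each intensity channel is sampled through
CHANNEL_CAMERA = {"r": "rgb", "g": "rgb", "b": "rgb", "nir780": "nir780", "nir940": "nir940"}


@dataclass
class LandmarkSet:
    """Indexed landmarks of one frame: 2D on the reference image, lifted 3D, validity."""

    indices: np.ndarray  # (L,) mesh indices in 0..467
    coords2d: np.ndarray  # (L, 2) px
    coords3d: np.ndarray  # (L, 3) m, NaN where invalid
    valid: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1)
        self.coords2d = np.asarray(self.coords2d, dtype=float).reshape(-1, 2)
        self.coords3d = np.asarray(self.coords3d, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)


@dataclass
class RigidTransform:
    """6-DoF rotation/translation pair with the least-squares fit residual."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


@dataclass
class RoiTrack:
    """Frame-1 ROI grid, per-frame transforms, and the transformed grids."""

    roi: ROI3D
    transforms: list[RigidTransform]
    grids: np.ndarray  # (T, h, w, 3)

    @property
    def n_frames(self) -> int:
        return len(self.transforms)


def _bilinear_cloud_sample(cloud: PointCloud, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample an organised cloud's (x, y, z) grids at fractional pixel coords.

    A sample is valid only when all four stencil neighbours carry depth."""
    H, W = cloud.valid.shape
    u, v = uv[:, 0], uv[:, 1]
    inb = np.isfinite(u) & np.isfinite(v) & (u >= 0) & (u <= W - 1) & (v >= 0) & (v <= H - 1)
    us = np.where(inb, u, 0.0)
    vs = np.where(inb, v, 0.0)
    x0 = np.minimum(np.floor(us).astype(int), max(W - 2, 0))
    y0 = np.minimum(np.floor(vs).astype(int), max(H - 2, 0))
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    ok = inb & cloud.valid[y0, x0] & cloud.valid[y0, x1] & cloud.valid[y1, x0] & cloud.valid[y1, x1]
    wx = (us - x0)[:, None]
    wy = (vs - y0)[:, None]
    c = cloud.coordinates
    pts = (
        c[y0, x0] * (1 - wx) * (1 - wy)
        + c[y0, x1] * wx * (1 - wy)
        + c[y1, x0] * (1 - wx) * wy
        + c[y1, x1] * wx * wy
    )
    pts = np.where(ok[:, None], pts, np.nan)
    return pts, ok


def lift_landmarks(
    landmarks2d: np.ndarray,
    indices: np.ndarray | Sequence[int],
    cloud: PointCloud,
) -> LandmarkSet:
    """Lift 2D landmarks on the reference image into the registered point cloud.

    Depth (and lateral position) are sampled bilinearly from the organised cloud;
    landmarks over holes are dropped but keep their index slot for correspondence
    bookkeeping.  Fewer than 3 valid lifted landmarks is an error.
    """
    landmarks2d = np.asarray(landmarks2d, dtype=float).reshape(-1, 2)
    pts3d, valid = _bilinear_cloud_sample(cloud, landmarks2d)
    if valid.sum() < 3:
        raise ValueError(f"only {int(valid.sum())} landmarks could be lifted (need >= 3)")
    return LandmarkSet(np.asarray(indices), landmarks2d, pts3d, valid)


def estimate_rigid_transform(P1: np.ndarray, Pk: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping ``P1`` onto ``Pk``.

    SVD of the centred cross-covariance with determinant-sign correction; no
    scale term (pure 6-DoF).  Requires >= 3 non-collinear corresponding pairs.
    """
    P1 = np.asarray(P1, dtype=float).reshape(-1, 3)
    Pk = np.asarray(Pk, dtype=float).reshape(-1, 3)
    if P1.shape != Pk.shape:
        raise ValueError("point sets must have matching shapes")
    n = P1.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 corresponding points, got {n}")
    c1 = P1.mean(axis=0)
    ck = Pk.mean(axis=0)
    A = P1 - c1
    B = Pk - ck
    # collinearity check on the source configuration
    s_cfg = np.linalg.svd(A, compute_uv=False)
    if s_cfg[1] <= 1e-12 * max(s_cfg[0], 1e-300):
        raise ValueError("degenerate (collinear) landmark configuration")
    M = A.T @ B
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = ck - R @ c1
    resid = P1 @ R.T + t - Pk
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, rms)


def track_roi(roi: ROI3D, landmark_sets: Sequence[LandmarkSet]) -> RoiTrack:
    """Carry the frame-1 ROI grid through the video via per-frame rigid transforms.

    Every frame is fitted against frame 1 on the index intersection of valid
    landmarks.  The frame-1 transform is the identity by construction.
    """
    if not landmark_sets:
        raise ValueError("no landmark sets supplied")
    ref = landmark_sets[0]
    transforms: list[RigidTransform] = []
    h, w = roi.shape
    grids = np.empty((len(landmark_sets), h, w, 3))
    flat = roi.points.reshape(-1, 3)
    for k, lmk in enumerate(landmark_sets):
        if k == 0:
            tr = RigidTransform.identity()
        else:
            common_ref, i1, ik = np.intersect1d(
                ref.indices[ref.valid], lmk.indices[lmk.valid], return_indices=True
            )
            if common_ref.size < 3:
                raise ValueError(
                    f"frame {k}: only {common_ref.size} landmarks shared with frame 1"
                )
            p1 = ref.coords3d[ref.valid][i1]
            pk = lmk.coords3d[lmk.valid][ik]
            tr = estimate_rigid_transform(p1, pk)
        transforms.append(tr)
        grids[k] = tr.apply(flat).reshape(h, w, 3)
    return RoiTrack(roi, transforms, grids)


def crop_roi_video(
    container,
    track: RoiTrack,
    cameras: Mapping[str, CameraModel],
    rect: np.ndarray,
    channels: Sequence[str] = ("r", "g", "b", "nir780", "nir940"),
    qc_invalid_fraction: float = 0.2,
):
    """Project the tracked ROI into every modality and sample fixed-size crops.

    Returns a :class:`camoxy.preprocess.RoiVideo` with data ``(C, T, h, w)``.
    Frames whose invalid-projection fraction exceeds ``qc_invalid_fraction`` are
    flagged in the QC log.  Holes are carried as a mask, not filled.
    """
    from .preprocess import RoiVideo  # local import to avoid a cycle

    T = track.n_frames
    if container.n_frames != T:
        raise ValueError("container and track are not synchronized")
    h, w = track.roi.shape
    data = np.full((len(channels), T, h, w), np.nan, dtype=float)
    valid = np.ones((T, h, w), dtype=bool)
    for name in channels:
        if name not in container.channels:
            raise ValueError(f"modality '{name}' missing from container")
        cam_name = CHANNEL_CAMERA[name]
        if cam_name not in cameras:
            raise ValueError(f"camera '{cam_name}' missing for modality '{name}'")
    base_ok = ~track.roi.holes
    for k in range(T):
        pts = track.grids[k].reshape(-1, 3)
        for ci, name in enumerate(channels):
            cam = cameras[CHANNEL_CAMERA[name]]
            px = project_points(pts, cam, rect)
            px.valid &= base_ok.reshape(-1)
            vals, ok = sample_bilinear(container.channels[name][k], px)
            data[ci, k] = vals.reshape(h, w)
            valid[k] &= ok.reshape(h, w)
    frame_invalid = 1.0 - valid.reshape(T, -1).mean(axis=1)
    qc_flagged = [int(k) for k in np.flatnonzero(frame_invalid > qc_invalid_fraction)]
    if qc_flagged:
        logger.warning(
            "%d/%d frames exceed %.0f%% invalid ROI projections: %s",
            len(qc_flagged), T, 100 * qc_invalid_fraction, qc_flagged[:10],
        )
    holes = ~valid.all(axis=0)  # static union of per-frame invalidity
    data = np.where(np.isnan(data), 0.0, data)
    return RoiVideo(
        data=data,
        channels=tuple(channels),
        fps=container.fps,
        timestamps=np.asarray(container.timestamps, dtype=float),
        holes=holes,
        frame_invalid_fraction=frame_invalid,
        qc_flagged_frames=qc_flagged,
        bit_depth=container.bit_depth,
    )


def anonymize(container, landmark_index_sets: Sequence[Sequence[int]], padding: int = 0):
    """Black out eye/mouth regions across all registered modalities, in place.

    For each frame and each designated landmark index set, the axis-aligned
    bounding box of those landmarks (padded by ``padding`` px, clipped to the
    image) is set to 0 in every intensity modality.  Returns the container.
    """
    sets = [np.asarray(s, dtype=int) for s in landmark_index_sets]
    if any(s.size == 0 for s in sets) or not sets:
        raise ValueError("landmark index sets must be nonempty")
    idx_lookup = {int(i): pos for pos, i in enumerate(container.landmark_indices)}
    T = container.n_frames
    any_stack = next(iter(container.channels.values()))
    H, W = any_stack.shape[1:]
    for k in range(T):
        pts = container.landmarks2d[k]
        for s in sets:
            rows = [idx_lookup[i] for i in s if int(i) in idx_lookup]
            if not rows:
                continue
            p = pts[rows]
            x0 = max(int(np.floor(p[:, 0].min())) - padding, 0)
            x1 = min(int(np.ceil(p[:, 0].max())) + padding, W - 1)
            y0 = max(int(np.floor(p[:, 1].min())) - padding, 0)
            y1 = min(int(np.ceil(p[:, 1].max())) + padding, H - 1)
            for stack in container.channels.values():
                stack[k, y0 : y1 + 1, x0 : x1 + 1] = 0
    return container


# ---------------------------------------------------------------------------
# SSIM tracking quality
# ---------------------------------------------------------------------------


def ssim_uniform(
    img1: np.ndarray,
    img2: np.ndarray,
    win_size: int = 7,
    data_range: float = 255.0,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean structural similarity with a uniform window and unbiased covariances.

    Border windows that would extend outside the image are excluded (equivalent
    to computing the SSIM map on 'valid' windows only).  Constant images are
    handled by the stabilising constants C1, C2 — no special-casing needed.
    """
    x = np.asarray(img1, dtype=float)
    y = np.asarray(img2, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("images must be 2D with matching shapes")
    if min(x.shape) < win_size:
        raise ValueError("image smaller than SSIM window")
    from numpy.lib.stride_tricks import sliding_window_view

    NP = win_size * win_size
    cov_norm = NP / (NP - 1)

    def wmean(a):
        return sliding_window_view(a, (win_size, win_size)).mean(axis=(-1, -2))

    ux, uy = wmean(x), wmean(y)
    uxx, uyy, uxy = wmean(x * x), wmean(y * y), wmean(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    ssim_map = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))
    return float(ssim_map.mean())


def tracking_ssim(crops, channel: str = "g", win_size: int = 7) -> np.ndarray:
    """SSIM of each frame's reference-channel crop against the frame-1 crop.

    A perfectly tracked, static ROI gives a flat series at 1.0; drift or residual
    motion shows up as a decaying series.
    """
    if channel not in crops.channels:
        raise ValueError(f"channel '{channel}' not in crops {crops.channels}")
    ci = crops.channels.index(channel)
    stack = crops.data[ci]
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    data_range = float(2**crops.bit_depth - 1)
    ref = stack[0]
    return np.array(
        [ssim_uniform(ref, stack[k], win_size=win_size, data_range=data_range)
         for k in range(stack.shape[0])]
    )
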
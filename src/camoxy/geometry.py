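"""Camera models, disparity back-projection, projection and multimodal registration.

The multimodal rig consists of a rectified active-stereo pair (which produces the
disparity maps consumed here), a colour camera and two narrowband NIR cameras
(780 nm, 940 nm).  All 3D quantities live in the *rectified reference frame*: the
frame of the stereo reference camera after rectification.  A 3D point ``p`` in that
frame projects into 2D camera ``c`` as

    s * [u, v, 1]^T = K_c * (R_c * R_rect^{-1} * p + T_c)

where ``(K_c, R_c, T_c)`` are the camera's intrinsics/extrinsics with respect to the
*unrectified* reference camera and ``R_rect`` is the stereo rectification rotation.
``s`` is the homogeneous normalisation factor; points with ``s <= 0`` lie behind the
camera and are flagged invalid.

Conventions (used consistently across the package):

* pixel indices are 0-based, ``(u, v) = (column, row)``, pixel centres at integers;
* bilinear samples that would require a neighbour outside the image are invalid
  (no clamping), so no gray value is ever fabricated at an ROI edge;
* holes (pixels without depth) are carried as masks, never interpolated away.

Lens distortion is assumed to be corrected upstream: the rig delivers rectified,
undistorted streams and the calibration file carries no distortion terms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "CameraModel",
    "StereoRig",
    "PointCloud",
    "PixelCoords",
    "ROI3D",
    "disparity_to_pointcloud",
    "project_points",
    "sample_bilinear",
    "roi_grid_from_rect",
    "register_multimodal",
    "load_calibration",
    "save_calibration",
    "write_ply",
]

_ORTHO_TOL = 1e-9


def _check_rotation(R: np.ndarray, name: str = "rotation") -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {R.shape}")
    if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
        raise ValueError(f"{name} is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError(f"{name} has determinant -1 (reflection)")
    return R


@dataclass
class CameraModel:
    """Pinhole camera: intrinsics ``K`` plus extrinsics ``(R, T)`` w.r.t. the
    unrectified reference camera, and the sensor size in pixels ``(width, height)``."""

    intrinsics: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int]
    name: str = "camera"

    def __post_init__(self) -> None:
        self.intrinsics = np.asarray(self.intrinsics, dtype=float)
        if self.intrinsics.shape != (3, 3):
            raise ValueError("intrinsics must be 3x3")
        if self.intrinsics[0, 0] <= 0 or self.intrinsics[1, 1] <= 0:
            raise ValueError("focal lengths must be positive")
        if abs(self.intrinsics[2, 2] - 1.0) > 1e-12 or np.any(self.intrinsics[[1, 2, 2], [0, 0, 1]] != 0):
            raise ValueError("intrinsics must be upper-triangular with K[2,2]=1")
        self.rotation = _check_rotation(self.rotation, "camera rotation")
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))

    @property
    def width(self) -> int:
        return self.image_size[0]

    @property
    def height(self) -> int:
        return self.image_size[1]


@dataclass
class StereoRig:
    """Rectified stereo pair that produced the disparity maps.

    ``rectified_focal`` (px) and ``baseline`` (m) convert disparity to depth via
    ``z = f * b / d``; ``rectification_rotation`` maps the unrectified reference
    frame into the rectified one.  The principal point of ``reference_camera`` is
    reused for the rectified camera.
    """

    rectified_focal: float
    baseline: float
    rectification_rotation: np.ndarray
    reference_camera: CameraModel

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.rectified_focal <= 0:
            raise ValueError("rectified focal length must be positive")
        self.rectification_rotation = _check_rotation(
            self.rectification_rotation, "rectification rotation"
        )

    @property
    def principal_point(self) -> tuple[float, float]:
        K = self.reference_camera.intrinsics
        return float(K[0, 2]), float(K[1, 2])


@dataclass
class PointCloud:
    """Organised or flat cloud in the rectified reference frame (metres).

    ``coordinates`` has shape ``(..., 3)``; ``valid`` the matching leading shape.
    ``values`` optionally carries one gray value per point per modality.
    """

    coordinates: np.ndarray
    valid: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.coordinates.shape[:-1] != self.valid.shape:
            raise ValueError("coordinates / validity shape mismatch")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_points(self) -> np.ndarray:
        return self.coordinates[self.valid]


@dataclass
class PixelCoords:
    """Fractional image coordinates ``(u, v)`` with a validity mask."""

    uv: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class ROI3D:
    """Row-major ``h x w`` grid of 3D points selected on the reference image."""

    points: np.ndarray  # (h, w, 3)
    holes: np.ndarray  # (h, w) bool, True where no depth was available
    rect: tuple[int, int, int, int]  # (x0, y0, h, w) on the reference image

    @property
    def shape(self) -> tuple[int, int]:
        return self.points.shape[:2]


def disparity_to_pointcloud(disparity: np.ndarray, rig: StereoRig) -> PointCloud:
    """Back-project a disparity map of the rectified pair into a 3D point cloud.

    For pixels with disparity ``d > 0``: ``z = f * b / d`` and ``(x, y)`` follow by
    back-projection through the rectified reference camera.  ``d <= 0`` (or
    non-finite) pixels are holes.
    """
    disparity = np.asarray(disparity, dtype=float)
    h, w = disparity.shape
    if (w, h) != rig.reference_camera.image_size:
        raise ValueError(
            f"disparity size {(w, h)} does not match rig reference camera "
            f"{rig.reference_camera.image_size}"
        )
    valid = np.isfinite(disparity) & (disparity > 0)
    f = rig.rectified_focal
    cx, cy = rig.principal_point
    z = np.full((h, w), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[valid] = f * rig.baseline / disparity[valid]
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = (uu - cx) * z / f
    y = (vv - cy) * z / f
    coords = np.stack([x, y, z], axis=-1)
    if not valid.any():
        warnings.warn("all-invalid disparity map: returning an empty cloud", stacklevel=2)
    return PointCloud(coords, valid)


def project_points(
    points: np.ndarray | PointCloud,
    camera: CameraModel,
    rect: np.ndarray | None = None,
) -> PixelCoords:
    """Project rectified-frame 3D points into a 2D camera.

    Implements ``s [u v 1]^T = K (R rect^{-1} p + T)``.  Points with projective
    depth ``s <= 0`` or landing outside the image bounds are invalid.
    """
    if isinstance(points, PointCloud):
        pts = points.coordinates
        base_valid = points.valid
    else:
        pts = np.asarray(points, dtype=float)
        base_valid = np.ones(pts.shape[:-1], dtype=bool)
    if rect is None:
        rect = np.eye(3)
    rect = _check_rotation(rect, "rectification rotation")
    K = camera.intrinsics
    if abs(np.linalg.det(K)) < 1e-15:
        raise ValueError("singular intrinsics matrix")
    lead = pts.shape[:-1]
    flat = pts.reshape(-1, 3)
    cam = flat @ (camera.rotation @ rect.T).T + camera.translation
    hom = cam @ K.T
    s = hom[:, 2]
    valid = base_valid.reshape(-1) & np.isfinite(s) & (s > 0)
    uv = np.full((flat.shape[0], 2), np.nan)
    np.divide(hom[:, :2], s[:, None], out=uv, where=valid[:, None])
    w, h = camera.image_size
    inb = valid & (uv[:, 0] >= 0) & (uv[:, 0] <= w - 1) & (uv[:, 1] >= 0) & (uv[:, 1] <= h - 1)
    return PixelCoords(uv.reshape(lead + (2,)), inb.reshape(lead))


def sample_bilinear(
    image: np.ndarray, coords: PixelCoords
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly sample ``image`` at fractional pixel coordinates.

    The value at ``(u, v)`` is the 4-neighbour blend.  Samples whose 4-neighbour
    stencil would leave the image, and samples already flagged invalid, are
    returned as NaN with ``valid=False``.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    uv = coords.uv.reshape(-1, 2)
    u, v = uv[:, 0], uv[:, 1]
    valid = (
        coords.valid.reshape(-1)
        & np.isfinite(u)
        & np.isfinite(v)
        & (u >= 0)
        & (u <= w - 1)
        & (v >= 0)
        & (v <= h - 1)
    )
    us = np.where(valid, u, 0.0)
    vs = np.where(valid, v, 0.0)
    # anchor so that u == w-1 lands on the last cell with weight 1 on its right edge
    x0 = np.minimum(np.floor(us).astype(int), max(w - 2, 0))
    y0 = np.minimum(np.floor(vs).astype(int), max(h - 2, 0))
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    wx = us - x0
    wy = vs - y0
    vals = (
        image[y0, x0] * (1 - wx) * (1 - wy)
        + image[y0, x1] * wx * (1 - wy)
        + image[y1, x0] * (1 - wx) * wy
        + image[y1, x1] * wx * wy
    )
    vals = np.where(valid, vals, np.nan)
    return vals.reshape(coords.valid.shape), valid.reshape(coords.valid.shape)


def roi_grid_from_rect(
    rect: tuple[int, int, int, int],
    cloud: PointCloud,
    max_hole_fraction: float = 0.5,
) -> ROI3D:
    """Select an ``h x w`` rectangle on the reference image and lift it to 3D.

    ``rect`` is ``(x0, y0, h, w)`` on the organised cloud's image grid.  Pixels
    without depth become holes; more than ``max_hole_fraction`` holes is an error.
    """
    x0, y0, h, w = (int(v) for v in rect)
    if cloud.coordinates.ndim != 3:
        raise ValueError("roi_grid_from_rect needs an organised (H, W, 3) cloud")
    H, W = cloud.valid.shape
    if x0 < 0 or y0 < 0 or y0 + h > H or x0 + w > W or h < 1 or w < 1:
        raise ValueError(f"rect {rect} not inside the {W}x{H} image")
    pts = cloud.coordinates[y0 : y0 + h, x0 : x0 + w].copy()
    holes = ~cloud.valid[y0 : y0 + h, x0 : x0 + w]
    frac = holes.mean()
    if frac > max_hole_fraction:
        raise ValueError(
            f"ROI rect {rect} has {frac:.0%} holes (> {max_hole_fraction:.0%})"
        )
    return ROI3D(pts, holes, (x0, y0, h, w))


def register_multimodal(
    points: ROI3D | PointCloud | np.ndarray,
    cameras: Mapping[str, CameraModel],
    images: Mapping[str, np.ndarray],
    rect: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Attach one gray value per modality to each 3D point.

    Each listed camera must come with a synchronised image under the same key.
    Returns ``{modality: (values, valid)}`` with the leading shape of ``points``.
    Registration is per-point (projection + bilinear sampling), so permuting the
    point order permutes the outputs identically.
    """
    if isinstance(points, ROI3D):
        pts = points.points
        base_valid = ~points.holes
    elif isinstance(points, PointCloud):
        pts = points.coordinates
        base_valid = points.valid
    else:
        pts = np.asarray(points, dtype=float)
        base_valid = np.ones(pts.shape[:-1], dtype=bool)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, camera in cameras.items():
        if name not in images:
            raise ValueError(f"missing image for camera '{name}'")
        px = project_points(pts, camera, rect)
        px.valid &= base_valid
        out[name] = sample_bilinear(images[name], px)
    return out


# ---------------------------------------------------------------------------
# Calibration file I/O
# ---------------------------------------------------------------------------

_CAM_FIELDS = ("name", "K", "R", "T", "width", "height")
_RIG_FIELDS = ("rect_R", "baseline_m", "rect_focal_px")


def calibration_to_dict(
    cameras: Mapping[str, CameraModel], rig: StereoRig, reference: str
) -> dict:
    return {
        "cameras": [
            {
                "name": name,
                "K": cam.intrinsics.reshape(9).tolist(),
                "R": cam.rotation.reshape(9).tolist(),
                "T": cam.translation.tolist(),
                "width": cam.width,
                "height": cam.height,
            }
            for name, cam in cameras.items()
        ],
        "rect_R": rig.rectification_rotation.reshape(9).tolist(),
        "baseline_m": rig.baseline,
        "rect_focal_px": rig.rectified_focal,
        "reference": reference,
    }


def calibration_from_dict(data: dict) -> tuple[dict[str, CameraModel], StereoRig, str]:
    for f in _RIG_FIELDS + ("cameras", "reference"):
        if f not in data:
            raise ValueError(f"calibration missing field '{f}'")
    cameras: dict[str, CameraModel] = {}
    for block in data["cameras"]:
        for f in _CAM_FIELDS:
            if f not in block:
                raise ValueError(f"camera block missing field '{f}'")
        cameras[block["name"]] = CameraModel(
            np.asarray(block["K"], dtype=float).reshape(3, 3),
            np.asarray(block["R"], dtype=float).reshape(3, 3),
            np.asarray(block["T"], dtype=float),
            (block["width"], block["height"]),
            name=block["name"],
        )
    ref = data["reference"]
    if ref not in cameras:
        raise ValueError(f"reference camera '{ref}' not among camera blocks")
    rig = StereoRig(
        float(data["rect_focal_px"]),
        float(data["baseline_m"]),
        np.asarray(data["rect_R"], dtype=float).reshape(3, 3),
        cameras[ref],
    )
    return cameras, rig, ref


def save_calibration(
    path: str | Path, cameras: Mapping[str, CameraModel], rig: StereoRig, reference: str
) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(cameras, rig, reference), indent=2))


def load_calibration(path: str | Path) -> tuple[dict[str, CameraModel], StereoRig, str]:
    return calibration_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PLY export
# ---------------------------------------------------------------------------


def write_ply(path: str | Path, cloud: PointCloud) -> int:
    """Export the valid points as binary little-endian PLY.

    ``x, y, z`` are float32; any per-modality values are written as extra float32
    properties named after the modality.  Returns the number of points written.
    """
    pts = cloud.valid_points().astype("<f4")
    props = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    extras = {}
    for name, vals in cloud.values.items():
        extras[name] = np.asarray(vals)[cloud.valid].astype("<f4")
        props.append((name, "<f4"))
    rec = np.empty(pts.shape[0], dtype=props)
    rec["x"], rec["y"], rec["z"] = pts[:, 0], pts[:, 1], pts[:, 2]
    for name, vals in extras.items():
        rec[name] = vals
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {pts.shape[0]}"]
    header += [f"property float {name}" for name, _ in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        rec.tofile(fh)
    return pts.shape[0]
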
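"""Geometry layer: projection, back-projection, sampling, registration, I/O."""

import json

import numpy as np
import pytest

from camoxy.geometry import (CameraModel, PixelCoords, PointCloud, StereoRig,
                             calibration_from_dict, calibration_to_dict,
                             disparity_to_pointcloud, load_calibration,
                             project_points, register_multimodal,
                             roi_grid_from_rect, sample_bilinear,
                             save_calibration, write_ply)


def _random_camera(rng, w=64, h=48):
    from scipy.spatial.transform import Rotation

    K = np.array([
        [rng.uniform(50, 500), 0, rng.uniform(10, w - 10)],
        [0, rng.uniform(50, 500), rng.uniform(10, h - 10)],
        [0, 0, 1.0],
    ])
    R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
    T = rng.normal(scale=0.1, size=3)
    return CameraModel(K, R, T, (w, h))


class TestProjectPoints:
    def test_identity_camera_homogeneous_normalisation(self):
        cam = CameraModel(np.eye(3), np.eye(3), np.zeros(3), (10, 10))
        px = project_points(np.array([[0.0, 0.0, 2.0]]), cam)
        assert np.allclose(px.uv[0], [0.0, 0.0])
        assert px.valid[0]

    def test_pinhole_formula(self):
        K = np.array([[500.0, 0, 320], [0, 500.0, 240], [0, 0, 1]])
        cam = CameraModel(K, np.eye(3), np.zeros(3), (640, 480))
        px = project_points(np.array([[0.1, 0.2, 1.0]]), cam)
        assert np.allclose(px.uv[0], [370.0, 340.0])

    def test_matches_homogeneous_matrix_oracle(self, rng):
        """1000 random camera/point draws vs direct 3x4-matrix evaluation."""
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            cam = _random_camera(rng, w=6400, h=4800)
            rect = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            pts = rng.normal(scale=2.0, size=(50, 3))
            px = project_points(pts, cam, rect)
            P = cam.intrinsics @ np.hstack(
                [cam.rotation @ rect.T, cam.translation[:, None]]
            )
            hom = np.hstack([pts, np.ones((50, 1))]) @ P.T
            expect = hom[:, :2] / hom[:, 2:3]
            ok = px.valid
            assert np.abs(px.uv[ok] - expect[ok]).max() <= 1e-9

    def test_negative_depth_invalid(self):
        cam = CameraModel(np.eye(3), np.eye(3), np.zeros(3), (10, 10))
        px = project_points(np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 0.0]]), cam)
        assert not px.valid.any()

    def test_singular_intrinsics_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            CameraModel(np.diag([0.0, 1, 1]), np.eye(3), np.zeros(3), (4, 4))

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            CameraModel(np.eye(3), np.eye(3) * 2, np.zeros(3), (4, 4))


class TestDisparity:
    def _rig(self, w=8, h=6, f=100.0, b=0.1):
        K = np.array([[f, 0, (w - 1) / 2], [0, f, (h - 1) / 2], [0, 0, 1.0]])
        cam = CameraModel(K, np.eye(3), np.zeros(3), (w, h))
        return StereoRig(f, b, np.eye(3), cam)

    def test_closed_form_depth_at_principal_point(self):
        rig = self._rig(w=9, h=7)  # integer principal point (4, 3)
        disp = np.zeros((7, 9))
        disp[3, 4] = 10.0
        cloud = disparity_to_pointcloud(disp, rig)
        assert cloud.valid[3, 4] and cloud.n_valid == 1
        assert np.allclose(cloud.coordinates[3, 4], [0.0, 0.0, 1.0])

    def test_zero_disparity_invalid(self):
        rig = self._rig()
        disp = np.zeros((6, 8))
        with pytest.warns(UserWarning, match="all-invalid"):
            cloud = disparity_to_pointcloud(disp, rig)
        assert cloud.n_valid == 0

    def test_roundtrip_reprojection(self, rng):
        """disparity -> cloud -> rectified projection reproduces pixels and
        disparity to < 1e-6 px for all valid pixels."""
        rig = self._rig(w=32, h=24)
        disp = rng.uniform(5.0, 40.0, size=(24, 32))
        disp[rng.random((24, 32)) < 0.2] = 0.0
        cloud = disparity_to_pointcloud(disp, rig)
        px = project_points(cloud, rig.reference_camera, rig.rectification_rotation)
        uu, vv = np.meshgrid(np.arange(32.0), np.arange(24.0))
        ok = cloud.valid
        assert np.abs(px.uv[ok][:, 0] - uu[ok]).max() < 1e-6
        assert np.abs(px.uv[ok][:, 1] - vv[ok]).max() < 1e-6
        d_back = rig.rectified_focal * rig.baseline / cloud.coordinates[ok][:, 2]
        assert np.abs(d_back - disp[ok]).max() < 1e-6

    def test_size_mismatch_error(self):
        rig = self._rig()
        with pytest.raises(ValueError, match="size"):
            disparity_to_pointcloud(np.ones((5, 5)), rig)


class TestBilinear:
    def test_integer_coords_exact(self, rng):
        img = rng.normal(size=(9, 11))
        uu, vv = np.meshgrid(np.arange(11.0), np.arange(9.0))
        coords = PixelCoords(np.stack([uu.ravel(), vv.ravel()], 1),
                             np.ones(99, dtype=bool))
        vals, ok = sample_bilinear(img, coords)
        assert ok.all()
        assert np.allclose(vals, img.ravel())

    def test_patch_centre_is_mean(self):
        img = np.array([[0.0, 2.0], [4.0, 6.0]])
        vals, ok = sample_bilinear(img, PixelCoords(np.array([[0.5, 0.5]]), np.array([True])))
        assert ok[0] and vals[0] == 3.0

    def test_matches_four_term_formula(self, rng):
        """10 000 random coordinates against the explicit bilinear blend."""
        img = rng.normal(size=(17, 23))
        u = rng.uniform(0, 22, size=10_000)
        v = rng.uniform(0, 16, size=10_000)
        vals, ok = sample_bilinear(img, PixelCoords(np.stack([u, v], 1),
                                                    np.ones(u.size, bool)))
        x0, y0 = np.floor(u).astype(int), np.floor(v).astype(int)
        x0, y0 = np.minimum(x0, 21), np.minimum(y0, 15)
        wx, wy = u - x0, v - y0
        expect = (img[y0, x0] * (1 - wx) * (1 - wy) + img[y0, x0 + 1] * wx * (1 - wy)
                  + img[y0 + 1, x0] * (1 - wx) * wy + img[y0 + 1, x0 + 1] * wx * wy)
        assert ok.all()
        assert np.abs(vals - expect).max() <= 1e-12

    def test_outside_border_flagged(self):
        img = np.ones((4, 4))
        coords = PixelCoords(np.array([[-0.1, 1.0], [3.5, 1.0], [1.0, 5.0]]),
                             np.ones(3, bool))
        vals, ok = sample_bilinear(img, coords)
        assert not ok.any()
        assert np.isnan(vals).all()


class TestRoiGrid:
    def _planar_cloud(self, h=20, w=24):
        uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        z = np.full((h, w), 2.0)
        coords = np.stack([(uu - w / 2) * 0.01, (vv - h / 2) * 0.01, z], axis=-1)
        return PointCloud(coords, np.ones((h, w), bool))

    def test_planar_cloud_grid_coplanar(self):
        cloud = self._planar_cloud()
        roi = roi_grid_from_rect((3, 2, 10, 12), cloud)
        pts = roi.points.reshape(-1, 3)
        centred = pts - pts.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        assert s[2] <= 1e-9  # plane-fit residual

    def test_single_pixel_rect(self):
        cloud = self._planar_cloud()
        roi = roi_grid_from_rect((5, 7, 1, 1), cloud)
        assert np.allclose(roi.points[0, 0], cloud.coordinates[7, 5])

    def test_hole_threshold_error(self):
        cloud = self._planar_cloud()
        cloud.valid[:] = False
        with pytest.raises(ValueError, match="holes"):
            roi_grid_from_rect((3, 2, 10, 12), cloud)

    def test_rect_outside_image_error(self):
        with pytest.raises(ValueError, match="not inside"):
            roi_grid_from_rect((20, 0, 10, 10), self._planar_cloud())


class TestRegisterMultimodal:
    def _setup(self, rng):
        K = np.array([[100.0, 0, 31.5], [0, 100.0, 23.5], [0, 0, 1]])
        cam = CameraModel(K, np.eye(3), np.zeros(3), (64, 48))
        img = rng.normal(size=(48, 64))
        pts = np.column_stack([rng.uniform(-0.1, 0.1, 30), rng.uniform(-0.08, 0.08, 30),
                               np.full(30, 1.0)])
        return cam, img, pts

    def test_identical_cameras_identical_values(self, rng):
        cam, img, pts = self._setup(rng)
        out = register_multimodal(pts, {"a": cam, "b": cam}, {"a": img, "b": img})
        va, oa = out["a"]
        vb, ob = out["b"]
        assert np.array_equal(oa, ob) and np.allclose(va[oa], vb[ob])

    def test_point_behind_camera_invalid_single_modality(self, rng):
        cam, img, pts = self._setup(rng)
        cam_flipped = CameraModel(cam.intrinsics, np.diag([1.0, -1.0, -1.0]),
                                  np.zeros(3), cam.image_size)
        pts[0, 2] = 1.0
        out = register_multimodal(pts, {"front": cam, "back": cam_flipped},
                                  {"front": img, "back": img})
        assert out["front"][1].any()
        assert not out["back"][1].any()  # everything is behind the flipped camera

    def test_missing_image_error(self, rng):
        cam, img, pts = self._setup(rng)
        with pytest.raises(ValueError, match="missing image"):
            register_multimodal(pts, {"a": cam}, {})

    def test_permutation_equivariance(self, rng):
        cam, img, pts = self._setup(rng)
        perm = rng.permutation(len(pts))
        v1, o1 = register_multimodal(pts, {"a": cam}, {"a": img})["a"]
        v2, o2 = register_multimodal(pts[perm], {"a": cam}, {"a": img})["a"]
        assert np.array_equal(o1[perm], o2)
        assert np.allclose(v1[perm][o2], v2[o2])

    def test_simulator_flat_scene_reflectance_recovered(self):
        """Registered NIR values equal the analytic rendered radiance (zero noise).

        A texture-free flat scene makes the radiance field spatially constant,
        so bilinear resampling is exact; only the float32 frame storage limits
        the agreement.  Points near the surface silhouette are excluded (their
        bilinear stencils blend with background)."""
        from camoxy.simulate import SimConfig, simulate_recording

        cfg = SimConfig(duration_s=2.0, breath_cycles=0, curvature_radius_m=np.inf,
                        noise_sigma=0.0, landmark_noise_px=0.0, texture_contrast=0.0,
                        n_texture_waves=0, n_markers=0, seed=3)
        container, gt = simulate_recording(cfg)
        cameras, rig, _ = container.cameras()
        cloud = disparity_to_pointcloud(container.disparity[0], rig)
        images = {m: container.channels[m][0] for m in ("nir780", "nir940")}
        cams = {m: cameras[m] for m in images}
        out = register_multimodal(cloud, cams, images, rig.rectification_rotation)
        c0 = np.array([0.0, 0.0, cfg.surface_distance_m])
        local = cloud.coordinates - c0
        ex, ey = cfg.surface_extent_m
        central = cloud.valid & (np.abs(local[..., 0]) < 0.4 * ex) \
            & (np.abs(local[..., 1]) < 0.4 * ey)
        for m in images:
            vals, ok = out[m]
            expect = gt.surface.radiance(local[..., 0], local[..., 1], 0.0,
                                         gt.spo2_at_frames[0], m)
            sel = central & ok
            assert sel.sum() > 1000
            assert np.abs(vals[sel] - expect[sel]).max() <= 1e-4


class TestCalibrationIO:
    def test_roundtrip(self, tmp_path, small_recording):
        container, _ = small_recording
        cameras, rig, ref = container.cameras()
        path = tmp_path / "calib.json"
        save_calibration(path, cameras, rig, ref)
        cams2, rig2, ref2 = load_calibration(path)
        assert ref2 == ref
        for name in cameras:
            assert np.allclose(cams2[name].intrinsics, cameras[name].intrinsics)
            assert np.allclose(cams2[name].rotation, cameras[name].rotation)
        assert np.allclose(rig2.rectification_rotation, rig.rectification_rotation)

    def test_missing_field_error(self):
        with pytest.raises(ValueError, match="baseline_m"):
            calibration_from_dict({"cameras": [], "rect_R": [], "rect_focal_px": 1,
                                   "reference": "rgb"})


class TestPlyExport:
    def test_trimesh_reads_back_points(self, tmp_path, rng):
        coords = rng.normal(size=(40, 3))
        valid = rng.random(40) > 0.2
        cloud = PointCloud(coords, valid, values={"nir780": rng.uniform(0, 255, 40)})
        path = tmp_path / "cloud.ply"
        n = write_ply(path, cloud)
        assert n == valid.sum()
        trimesh = pytest.importorskip("trimesh")
        mesh = trimesh.load(str(path), process=False)
        assert np.allclose(np.asarray(mesh.vertices), coords[valid], atol=1e-6)
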
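"""Rigid-transform estimation, ROI tracking, cropping, anonymisation, SSIM."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from camoxy.geometry import disparity_to_pointcloud, roi_grid_from_rect
from camoxy.pipeline import PipelineConfig, process_recording
from camoxy.preprocess import CHANNEL_ORDER
from camoxy.tracking import (anonymize, crop_roi_video, estimate_rigid_transform,
                             lift_landmarks, ssim_uniform, track_roi, tracking_ssim)

from conftest import make_flat_container


def _objective(R, t, P1, Pk):
    return float(np.sum((P1 @ R.T + t - Pk) ** 2))


class TestRigidTransform:
    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        tr = estimate_rigid_transform(P, P)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)
        assert tr.residual_rms <= 1e-12

    def test_construct_and_recover(self, rng):
        P1 = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        t = np.array([5e-3, -3e-3, 2e-3])
        tr = estimate_rigid_transform(P1, P1 @ R.T + t)
        assert np.abs(tr.rotation - R).max() <= 1e-9
        assert np.abs(tr.translation - t).max() <= 1e-9

    def test_matches_scipy_umeyama_oracle(self, rng):
        """Closed-form solution equals scipy's independent Kabsch solver."""
        for _ in range(50):
            P1 = rng.normal(size=(8, 3))
            Pk = rng.normal(size=(8, 3))
            tr = estimate_rigid_transform(P1, Pk)
            rot, _ = Rotation.align_vectors(Pk - Pk.mean(0), P1 - P1.mean(0))
            assert np.abs(tr.rotation - rot.as_matrix()).max() <= 1e-9

    def test_noisy_fit_beats_random_perturbations(self, rng):
        P1 = rng.normal(scale=0.05, size=(468, 3))
        R = Rotation.from_euler("xyz", [3, -2, 5], degrees=True).as_matrix()
        t = np.array([0.004, 0.002, -0.006])
        Pk = P1 @ R.T + t + rng.normal(scale=5e-4, size=P1.shape)
        tr = estimate_rigid_transform(P1, Pk)
        base = _objective(tr.rotation, tr.translation, P1, Pk)
        for _ in range(500):
            dR = Rotation.from_rotvec(rng.normal(scale=1e-3, size=3)).as_matrix()
            dt = rng.normal(scale=1e-4, size=3)
            assert base <= _objective(dR @ tr.rotation, tr.translation + dt, P1, Pk) + 1e-15

    def test_collinear_configuration_error(self, rng):
        line = np.outer(np.linspace(0, 1, 5), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid_transform(line, line)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_rigid_transform(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_reflection_degenerate_still_proper_rotation(self, rng):
        """Even reflective/noisy configurations yield det(R) = +1."""
        P1 = rng.normal(size=(4, 3))
        Pk = -P1 + rng.normal(scale=0.01, size=P1.shape)  # reflection-like target
        tr = estimate_rigid_transform(P1, Pk)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0, atol=1e-9)

    def test_composition_consistency(self, rng):
        """Direct 1->k equals 1->j composed with a j->k refit on rigid data."""
        P1 = rng.normal(scale=0.05, size=(20, 3))
        Rj = Rotation.from_euler("xyz", [2, 1, -3], degrees=True).as_matrix()
        tj = np.array([0.002, -0.001, 0.003])
        Rk = Rotation.from_euler("xyz", [-1, 4, 2], degrees=True).as_matrix()
        tk = np.array([-0.002, 0.002, 0.001])
        Pj = P1 @ Rj.T + tj
        Pk = P1 @ Rk.T + tk
        tr_jk = estimate_rigid_transform(Pj, Pk)
        tr_1k = estimate_rigid_transform(P1, Pk)
        composed = Pj @ tr_jk.rotation.T + tr_jk.translation
        direct = P1 @ tr_1k.rotation.T + tr_1k.translation
        assert np.abs(composed - direct).max() <= 1e-8


class TestLiftAndTrack:
    def test_lift_exact_on_flat_noiseless_simulation(self, flat_noiseless_recording):
        container, gt = flat_noiseless_recording
        _, rig, _ = container.cameras()
        for k in (0, 30, 59):
            cloud = disparity_to_pointcloud(container.disparity[k], rig)
            lm = lift_landmarks(container.landmarks2d[k], container.landmark_indices, cloud)
            err = np.abs(lm.coords3d[lm.valid] - gt.landmarks3d[k][lm.valid])
            assert err.max() <= 1e-6

    def test_landmark_on_hole_dropped(self, rng):
        from camoxy.geometry import PointCloud

        coords = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (10, 10, 3)).copy()
        valid = np.ones((10, 10), bool)
        valid[4:6, 4:6] = False
        cloud = PointCloud(coords, valid)
        lm2d = np.array([[1.0, 1.0], [4.5, 4.5], [8.0, 8.0], [2.0, 7.0]])
        lm = lift_landmarks(lm2d, np.arange(4), cloud)
        assert list(lm.valid) == [True, False, True, True]

    def test_too_few_liftable_landmarks_error(self):
        from camoxy.geometry import PointCloud

        cloud = PointCloud(np.zeros((5, 5, 3)), np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="landmarks"):
            lift_landmarks(np.array([[2.0, 2.0], [3.0, 3.0], [1.0, 1.0]]),
                           np.arange(3), cloud)

    def test_static_landmarks_constant_roi(self, flat_container):
        container = flat_container
        _, rig, _ = container.cameras()
        cloud = disparity_to_pointcloud(container.disparity[0], rig)
        sets = [lift_landmarks(container.landmarks2d[k], container.landmark_indices, cloud)
                for k in range(5)]
        roi = roi_grid_from_rect((4, 4, 12, 16), cloud)
        track = track_roi(roi, sets)
        for k in range(5):
            assert np.allclose(track.grids[k], track.grids[0], atol=1e-12)
            assert np.allclose(track.transforms[k].rotation, np.eye(3), atol=1e-9)

    def test_tracked_roi_matches_ground_truth_motion(self, flat_noiseless_recording):
        """Tracked grids equal the ground-truth rigid motion of the frame-1 grid."""
        container, gt = flat_noiseless_recording
        _, rig, _ = container.cameras()
        sets = []
        roi = None
        for k in range(container.n_frames):
            cloud = disparity_to_pointcloud(container.disparity[k], rig)
            sets.append(lift_landmarks(container.landmarks2d[k],
                                       container.landmark_indices, cloud))
            if k == 0:
                roi = roi_grid_from_rect(gt.roi_rect, cloud)
        track = track_roi(roi, sets)
        flat = roi.points.reshape(-1, 3)
        for k in (10, 30, 59):
            expect = flat @ gt.rotations[k].T + gt.translations[k]
            assert np.abs(track.grids[k].reshape(-1, 3) - expect).max() <= 1e-6

    def test_landmark_subset_gives_same_transform(self, flat_noiseless_recording):
        container, gt = flat_noiseless_recording
        _, rig, _ = container.cameras()
        clouds = [disparity_to_pointcloud(container.disparity[k], rig) for k in (0, 40)]
        sets = [lift_landmarks(container.landmarks2d[k], container.landmark_indices, c)
                for k, c in zip((0, 40), clouds)]
        full = estimate_rigid_transform(sets[0].coords3d[sets[0].valid],
                                        sets[1].coords3d[sets[1].valid])
        half = estimate_rigid_transform(sets[0].coords3d[sets[0].valid][::2],
                                        sets[1].coords3d[sets[1].valid][::2])
        assert np.abs(full.rotation - half.rotation).max() <= 1e-6
        assert np.abs(full.translation - half.translation).max() <= 1e-6


class TestCrop:
    def _track(self, container, rect=(4, 4, 12, 16), n=None):
        _, rig, _ = container.cameras()
        cloud = disparity_to_pointcloud(container.disparity[0], rig)
        n = n or container.n_frames
        sets = [lift_landmarks(container.landmarks2d[k], container.landmark_indices,
                               disparity_to_pointcloud(container.disparity[k], rig))
                for k in range(n)]
        return track_roi(roi_grid_from_rect(rect, cloud), sets)

    def test_static_scene_crops_identical(self, flat_container):
        container = flat_container
        cameras, rig, _ = container.cameras()
        track = self._track(container)
        crops = crop_roi_video(container, track, cameras, rig.rectification_rotation)
        assert crops.data.shape == (5, container.n_frames, 12, 16)
        for k in range(1, container.n_frames):
            assert np.array_equal(crops.data[:, k], crops.data[:, 0])
        assert not crops.holes.any()

    def test_missing_modality_error(self, flat_container):
        container = flat_container
        cameras, rig, _ = container.cameras()
        track = self._track(container)
        del container.channels["nir940"]
        with pytest.raises(ValueError, match="nir940"):
            crop_roi_video(container, track, cameras, rig.rectification_rotation)

    def test_moving_head_crop_tracks_material_point(self, flat_noiseless_recording):
        """Each crop pixel follows one material point: values stay at the
        analytic radiance of that fixed point despite head motion."""
        container, gt = flat_noiseless_recording
        cameras, rig, _ = container.cameras()
        track = self._track(container, rect=gt.roi_rect)
        crops = crop_roi_video(container, track, cameras, rig.rectification_rotation)
        c0 = np.array([0.0, 0.0, 1.5])
        local = track.roi.points.reshape(-1, 3) - c0  # material coords (flat surface)
        times = container.timestamps
        for ci, ch in enumerate(CHANNEL_ORDER):
            for k in (0, 25, 50):
                expect = gt.surface.radiance(local[:, 0], local[:, 1], times[k],
                                             gt.spo2_at_frames[k], ch)
                got = crops.data[ci, k].reshape(-1)
                ok = ~np.isnan(got)
                # bilinear resampling of the textured render dominates the error
                assert np.median(np.abs(got - expect)) <= 2.0

    def test_qc_flags_frames_with_many_invalid(self, flat_container):
        container = flat_container
        cameras, rig, _ = container.cameras()
        track = self._track(container)
        track.grids[3] += np.array([0.0, 0.0, -2.5])  # push frame 3 behind the camera
        crops = crop_roi_video(container, track, cameras, rig.rectification_rotation)
        assert 3 in crops.qc_flagged_frames


class TestAnonymize:
    def test_boxes_zeroed_and_outside_untouched(self):
        container = make_flat_container(T=4)
        before = {c: container.channels[c].copy() for c in container.channels}
        eye_idx = [0, 1]
        anonymize(container, [eye_idx], padding=1)
        pts = container.landmarks2d[0][[0, 1]]
        x0 = int(np.floor(pts[:, 0].min())) - 1
        x1 = int(np.ceil(pts[:, 0].max())) + 1
        y0 = int(np.floor(pts[:, 1].min())) - 1
        y1 = int(np.ceil(pts[:, 1].max())) + 1
        for c, stack in container.channels.items():
            assert np.all(stack[:, y0:y1 + 1, x0:x1 + 1] == 0)
            outside = before[c].copy()
            outside[:, y0:y1 + 1, x0:x1 + 1] = 0
            expected = before[c].copy()
            expected[:, y0:y1 + 1, x0:x1 + 1] = 0
            assert np.array_equal(stack, expected)

    def test_single_landmark_zero_padding_is_one_pixel(self):
        container = make_flat_container(T=2)
        anonymize(container, [[5]], padding=0)
        u, v = container.landmarks2d[0][5]
        x0, y0 = int(np.floor(u)), int(np.floor(v))
        box = container.channels["r"][0, y0:int(np.ceil(v)) + 1, x0:int(np.ceil(u)) + 1]
        assert np.all(box == 0)

    def test_empty_index_set_error(self):
        container = make_flat_container(T=2)
        with pytest.raises(ValueError, match="nonempty"):
            anonymize(container, [[]])


class TestSSIM:
    def test_identical_images_unity(self, rng):
        img = rng.uniform(0, 255, size=(24, 24))
        assert ssim_uniform(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_image_low(self, rng):
        img = rng.uniform(0, 255, size=(24, 24))
        assert ssim_uniform(img, 255 - img) < 0.5

    def test_matches_skimage_oracle(self, rng):
        skimage_metrics = pytest.importorskip("skimage.metrics")
        for _ in range(5):
            a = rng.uniform(0, 255, size=(20, 26))
            b = a + rng.normal(scale=20, size=a.shape)
            mine = ssim_uniform(a, b, win_size=7, data_range=255.0)
            ref = skimage_metrics.structural_similarity(
                a, b, win_size=7, gaussian_weights=False, data_range=255.0)
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_tracking_ssim_series(self):
        container = make_flat_container(T=4)
        cameras, rig, _ = container.cameras()
        cloud = disparity_to_pointcloud(container.disparity[0], rig)
        sets = [lift_landmarks(container.landmarks2d[k], container.landmark_indices, cloud)
                for k in range(4)]
        track = track_roi(roi_grid_from_rect((4, 4, 12, 16), cloud), sets)
        crops = crop_roi_video(container, track, cameras, rig.rectification_rotation)
        series = tracking_ssim(crops)
        assert series.shape == (4,)
        assert np.allclose(series, 1.0, atol=1e-9)
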
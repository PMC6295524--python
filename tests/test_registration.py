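"""Homography estimation, canvas chaining and projection-error QC."""

import numpy as np
import pytest

from arenatrack import synth
from arenatrack.registration import (CameraRegistration, CorrespondenceSet,
                                     apply_homography, build_canvas,
                                     estimate_homography_ransac,
                                     fit_homography_dlt, load_registrations,
                                     match_features, projection_error,
                                     save_registrations, warp_point)


def random_homography(rng, perspective=1e-3):
    H = np.eye(3)
    H[:2, :2] += rng.uniform(-0.3, 0.3, size=(2, 2))
    H[:2, 2] = rng.uniform(-50, 50, size=2)
    H[2, :2] = rng.uniform(-perspective, perspective, size=2)
    return H


def rel_error(H_est, H_true):
    a = H_est / H_est[2, 2]
    b = H_true / H_true[2, 2]
    return np.linalg.norm(a - b) / np.linalg.norm(b)


class TestDlt:
    def test_recovers_random_homographies_from_exact_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            H = random_homography(rng)
            src = rng.uniform(0, 300, size=(12, 2))
            dst = apply_homography(H, src)
            assert rel_error(fit_homography_dlt(src, dst), H) < 1e-9

    def test_four_points_exact(self):
        rng = np.random.default_rng(1)
        H = random_homography(rng)
        src = np.array([[0.0, 0], [100, 0], [100, 80], [0, 80]])
        dst = apply_homography(H, src)
        H_est = fit_homography_dlt(src, dst)
        assert np.allclose(apply_homography(H_est, src), dst, atol=1e-8)

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(ValueError):
            fit_homography_dlt(np.zeros((3, 2)), np.zeros((3, 2)))


class TestApplyHomography:
    def test_identity(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(apply_homography(np.eye(3), pts), pts)

    def test_point_at_infinity_rejected(self):
        H = np.eye(3)
        H[2] = [1.0, 0.0, 0.0]  # w = x vanishes at x = 0
        with pytest.raises(ValueError):
            apply_homography(H, np.array([[0.0, 5.0]]))


class TestRansac:
    def test_noiseless_with_outliers_recovers_homography(self):
        rng = np.random.default_rng(2)
        H = random_homography(rng)
        src = rng.uniform(0, 400, size=(60, 2))
        dst = apply_homography(H, src)
        n_out = 18
        dst[:n_out] += rng.uniform(30, 90, size=(n_out, 2))
        corr = CorrespondenceSet("a", "b", src, dst)
        H_est, inliers = estimate_homography_ransac(corr, inlier_threshold=2.0, seed=4)
        assert rel_error(H_est, H) < 1e-6
        assert not inliers[:n_out].any()
        assert inliers[n_out:].all()

    def test_agrees_with_skimage_ransac_under_noise(self):
        from skimage.measure import ransac as sk_ransac
        from skimage.transform import ProjectiveTransform
        rng = np.random.default_rng(3)
        H = random_homography(rng)
        src = rng.uniform(0, 400, size=(80, 2))
        dst = apply_homography(H, src) + rng.normal(0, 0.3, size=(80, 2))
        H_est, _ = estimate_homography_ransac(
            CorrespondenceSet("a", "b", src, dst), inlier_threshold=2.0, seed=0)
        model, _ = sk_ransac((src, dst), ProjectiveTransform, min_samples=4,
                             residual_threshold=2.0, max_trials=500, rng=0)
        assert rel_error(H_est, model.params) < 2e-3

    def test_too_few_correspondences_rejected(self):
        with pytest.raises(ValueError):
            estimate_homography_ransac(
                CorrespondenceSet("a", "b", np.zeros((3, 2)), np.zeros((3, 2))))


def pairwise_correspondences(cameras, rng, n=80, noise_px=0.0,
                             extent=(0.0, 60.0, 0.0, 60.0)):
    """Exact (or noisy) matched pixel pairs for every overlapping camera pair."""
    pts = np.column_stack([rng.uniform(extent[0], extent[1], n),
                           rng.uniform(extent[2], extent[3], n)])
    corrs = []
    for i, a in enumerate(cameras):
        for b in cameras[i + 1:]:
            both = a.in_view(pts) & b.in_view(pts)
            if both.sum() < 8:
                continue
            pa = a.project(pts[both]) + rng.normal(0, noise_px, (both.sum(), 2))
            pb = b.project(pts[both]) + rng.normal(0, noise_px, (both.sum(), 2))
            corrs.append(CorrespondenceSet(a.camera_id, b.camera_id, pa, pb))
    return corrs


class TestBuildCanvas:
    def test_chained_registrations_are_mutually_consistent(self, four_camera_rig):
        rng = np.random.default_rng(5)
        corrs = pairwise_correspondences(four_camera_rig, rng, n=150)
        regs = build_canvas(corrs, four_camera_rig[0].camera_id, seed=0)
        pts = np.column_stack([rng.uniform(10, 50, 40), rng.uniform(10, 50, 40)])
        canvas = {}
        for cam in four_camera_rig:
            vis = cam.in_view(pts)
            px = cam.project(pts[vis])
            canvas[cam.camera_id] = (vis, apply_homography(
                regs[cam.camera_id].homography, px))
        # every point seen by >= 2 cameras lands on the same canvas position
        for i in range(len(pts)):
            seen = [canvas[c][1][canvas[c][0][:i + 1].sum() - 1]
                    for c in canvas if canvas[c][0][i]]
            if len(seen) >= 2:
                spread = np.max(np.linalg.norm(np.array(seen) - np.mean(seen, axis=0),
                                               axis=1))
                assert spread < 1e-6

    def test_landmark_sets_metric_scale(self, four_camera_rig):
        rng = np.random.default_rng(6)
        ref = four_camera_rig[0]
        corrs = pairwise_correspondences(four_camera_rig, rng, n=150)
        lm_cm = np.array([[15.0, 15.0], [35.0, 15.0]])  # 20 cm apart
        regs = build_canvas(corrs, ref.camera_id,
                            landmark_px=ref.project(lm_cm), landmark_cm=20.0, seed=0)
        p = apply_homography(regs[ref.camera_id].homography, ref.project(lm_cm))
        assert np.linalg.norm(p[1] - p[0]) == pytest.approx(20.0, rel=1e-9)
        # distances parallel to the landmark are metric across the whole canvas
        q_cm = np.array([[12.0, 18.0], [19.0, 18.0], [26.0, 18.0]])
        q = apply_homography(regs[ref.camera_id].homography, ref.project(q_cm))
        d_true = np.linalg.norm(q_cm[1:] - q_cm[:-1], axis=1)
        d_canvas = np.linalg.norm(q[1:] - q[:-1], axis=1)
        assert np.allclose(d_canvas, d_true, rtol=1e-6)

    def test_disconnected_rig_raises_naming_components(self, four_camera_rig):
        rng = np.random.default_rng(7)
        corrs = pairwise_correspondences(four_camera_rig, rng, n=150)
        left = {four_camera_rig[0].camera_id, four_camera_rig[1].camera_id}
        # keep only within-half overlaps: two islands, no bridge
        corrs = [c for c in corrs
                 if (c.camera_a in left) == (c.camera_b in left)]
        with pytest.raises(ValueError, match="disconnected"):
            build_canvas(corrs, four_camera_rig[0].camera_id, seed=0)

    def test_reference_registration_with_no_scale_is_pixel_identity(self, four_camera_rig):
        rng = np.random.default_rng(8)
        corrs = pairwise_correspondences(four_camera_rig, rng, n=150)
        regs = build_canvas(corrs, four_camera_rig[0].camera_id, seed=0)
        H = regs[four_camera_rig[0].camera_id].homography
        assert np.allclose(H / H[2, 2], np.eye(3), atol=1e-12)


class TestProjectionError:
    def test_two_cameras_with_known_offset_split_the_error(self):
        regs = {"a": CameraRegistration("a", np.eye(3)),
                "b": CameraRegistration("b", np.eye(3))}
        obs = {"a": {0: np.array([10.0, 10.0])},
               "b": {0: np.array([12.0, 10.0])}}  # 2 apart -> each 1 from mean
        rep = projection_error(obs, regs)
        assert rep.per_camera_median["a"] == pytest.approx(1.0)
        assert rep.overall_max == pytest.approx(1.0)

    def test_single_observer_points_skipped(self):
        regs = {"a": CameraRegistration("a", np.eye(3)),
                "b": CameraRegistration("b", np.eye(3))}
        obs = {"a": {0: np.array([1.0, 1.0]), 1: np.array([2.0, 2.0])},
               "b": {0: np.array([1.0, 1.0])}}
        rep = projection_error(obs, regs)
        assert rep.skipped_points == [1]

    def test_perfect_registration_zero_error(self, four_camera_rig):
        rng = np.random.default_rng(9)
        regs = {c.camera_id: CameraRegistration(c.camera_id,
                                                np.linalg.inv(c.homography))
                for c in four_camera_rig}
        pts = np.column_stack([rng.uniform(5, 55, 30), rng.uniform(5, 55, 30)])
        obs = {c.camera_id: {i: c.project(pts[i:i + 1])[0]
                             for i in range(len(pts)) if c.in_view(pts[i:i + 1])[0]}
               for c in four_camera_rig}
        rep = projection_error(obs, regs)
        assert rep.overall_max < 1e-9


class TestFeatureMatching:
    def test_calibration_scene_yields_registrable_matches(self, four_camera_rig,
                                                          small_arena):
        frames, _ = synth.generate_calibration_scene(four_camera_rig, small_arena,
                                                     seed=3)
        a, b = four_camera_rig[0], four_camera_rig[1]
        corr = match_features(frames[a.camera_id], frames[b.camera_id],
                              a.camera_id, b.camera_id)
        assert corr.registrable
        H_ab, inliers = estimate_homography_ransac(corr, inlier_threshold=3.0, seed=0)
        assert inliers.sum() >= 10
        # matched homography agrees with ground truth over the shared view
        H_true = b.homography @ np.linalg.inv(a.homography)
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 60, 200), rng.uniform(0, 60, 200)])
        both = a.in_view(pts) & b.in_view(pts)
        pa = a.project(pts[both])
        err = np.linalg.norm(apply_homography(H_ab, pa)
                             - apply_homography(H_true, pa), axis=1)
        assert np.median(err) < 1.5  # px


def test_save_load_round_trip(tmp_path, four_camera_rig):
    regs = {c.camera_id: CameraRegistration(
        c.camera_id, np.linalg.inv(c.homography), inlier_count=42,
        canvas_bounds=(0.0, 60.0, 0.0, 60.0), cm_per_px=0.2)
        for c in four_camera_rig}
    path = tmp_path / "regs.json"
    save_registrations(regs, path)
    loaded = load_registrations(path)
    assert set(loaded) == set(regs)
    for cid in regs:
        assert np.allclose(loaded[cid].homography, regs[cid].homography)
        assert loaded[cid].inlier_count == 42
        assert loaded[cid].canvas_bounds == (0.0, 60.0, 0.0, 60.0)


def test_warp_point_round_trip(four_camera_rig):
    cam = four_camera_rig[0]
    reg = CameraRegistration(cam.camera_id, np.linalg.inv(cam.homography))
    p_cm = np.array([22.0, 31.0])
    px = cam.project(p_cm[None, :])[0]
    assert np.allclose(warp_point(px, reg)[0], p_cm, atol=1e-9)
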
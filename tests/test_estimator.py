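"""Pose-estimator accuracy, confidence semantics and failure handling."""

import numpy as np
import pytest

from headposture import (
    EstimatorConfig,
    HeadPose,
    LandmarkObservation,
    LandmarkPoseModel,
    compute_confidence,
    estimate_distance,
    estimate_pose,
    euler_to_rotation,
    initialize_weak_perspective,
    make_subject,
    project,
    refine_pose,
    rotation_to_euler,
)
from headposture.exceptions import DegenerateConfigurationError, NotTrackedError

from conftest import noisy_observation


class TestWeakPerspectiveInit:
    def test_frontal_pose_recovered_coarsely(self, model, camera):
        truth = HeadPose(tz_mm=1200.0)
        init = initialize_weak_perspective(project(model, truth, camera),
                                           model, camera)
        assert np.max(np.abs(init.angles_deg)) < 2.0
        assert abs(init.tz_mm - 1200.0) / 1200.0 < 0.05

    def test_yawed_pose_within_basin(self, model, camera):
        truth = HeadPose(yaw_deg=20.0, tz_mm=1200.0)
        init = initialize_weak_perspective(project(model, truth, camera),
                                           model, camera)
        assert abs(init.yaw_deg - 20.0) < 5.0

    def test_too_few_landmarks_rejected(self, model, camera):
        obs = project(model, HeadPose(tz_mm=1200.0), camera)
        vis = np.zeros(68, dtype=bool)
        vis[:5] = True
        sparse = LandmarkObservation(0, obs.points_px, vis)
        with pytest.raises(DegenerateConfigurationError):
            initialize_weak_perspective(sparse, model, camera)

    def test_collinear_landmarks_rejected(self, model, camera):
        # a visible subset whose 3D positions are collinear cannot anchor
        # a 6-DoF pose: force it by placing the visible points on a line
        import dataclasses

        pts3 = model.points.copy()
        for i in range(8):
            pts3[i] = (10.0 * i, 0.0, 0.0)
        degenerate = dataclasses.replace(model, points=pts3)
        obs = project(model, HeadPose(tz_mm=1200.0), camera)
        vis = np.zeros(68, dtype=bool)
        vis[:8] = True
        with pytest.raises(DegenerateConfigurationError):
            initialize_weak_perspective(
                LandmarkObservation(0, obs.points_px, vis), degenerate, camera)


class TestRefineAndEstimate:
    def test_noiseless_exact_recovery(self, model, camera, cfg):
        truth = HeadPose(25.0, -10.0, 5.0, 0.0, 0.0, 1100.0)
        res = estimate_pose(project(model, truth, camera), model, camera, cfg)
        assert res.tracked
        assert np.max(np.abs(res.pose.angles_deg - truth.angles_deg)) < 1e-3
        assert np.max(np.abs(res.pose.translation_mm
                             - truth.translation_mm)) < 1e-2
        assert res.confidence > 1.0 - 1e-6

    def test_noise_mc_mean_error_below_one_degree(self, model, camera_f1000,
                                                  cfg):
        truth = HeadPose(25.0, -10.0, 5.0, 0.0, 0.0, 1200.0)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(200):
            obs = noisy_observation(model, truth, camera_f1000, 1.0, rng)
            res = estimate_pose(obs, model, camera_f1000, cfg)
            errs.append(np.abs(res.pose.angles_deg - truth.angles_deg))
        assert np.mean(errs) < 1.0

    def test_fully_occluded_frame_untracked(self, model, camera, cfg):
        obs = LandmarkObservation(0, np.full((68, 2), np.nan),
                                  np.zeros(68, dtype=bool))
        res = estimate_pose(obs, model, camera, cfg)
        assert not res.tracked
        assert np.all(np.isnan(res.pose.angles_deg))

    def test_half_occluded_noiseless_still_accurate(self, model, camera, cfg):
        truth = HeadPose(10.0, 5.0, -3.0, 0.0, 0.0, 1200.0)
        obs = project(model, truth, camera)
        rng = np.random.default_rng(3)
        vis = rng.random(68) >= 0.5
        assert vis.sum() >= 6
        res = estimate_pose(LandmarkObservation(0, obs.points_px, vis),
                            model, camera, cfg)
        assert res.tracked
        assert np.max(np.abs(res.pose.angles_deg - truth.angles_deg)) < 0.5

    def test_pure_noise_frames_never_track(self, model, camera, cfg):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.column_stack([rng.uniform(0, 1920, 68),
                                   rng.uniform(0, 1080, 68)])
            res = estimate_pose(LandmarkObservation(0, pts,
                                                    np.ones(68, dtype=bool)),
                                model, camera, cfg)
            assert not res.tracked

    def test_noise_monotonicity_small(self, model, camera_f1000, cfg):
        truth = HeadPose(15.0, -5.0, 8.0, 0.0, 0.0, 1200.0)
        means = []
        for sd in (0.5, 2.0, 8.0):
            rng = np.random.default_rng(11)
            errs = [np.abs(estimate_pose(
                noisy_observation(model, truth, camera_f1000, sd, rng),
                model, camera_f1000, cfg).pose.angles_deg
                - truth.angles_deg).mean() for _ in range(25)]
            means.append(np.mean(errs))
        assert means[0] <= means[1] <= means[2]

    def test_rotation_composition_consistency(self, model, camera, cfg):
        # estimating a frame of the pre-rotated rigid shape at the null
        # pose must recover the rotation that was applied to the shape
        import dataclasses

        rng = np.random.default_rng(21)
        for _ in range(10):
            yaw, pitch, roll = rng.uniform([-25, -15, -30], [25, 15, 30])
            truth = HeadPose(yaw, pitch, roll, 0.0, 0.0, 1200.0)
            R = euler_to_rotation(truth)
            rotated = dataclasses.replace(model, points=model.points @ R.T)
            obs = project(rotated, HeadPose(tz_mm=1200.0), camera)
            res = estimate_pose(obs, model, camera, cfg)
            assert res.tracked
            assert np.max(np.abs(res.pose.angles_deg
                                 - truth.angles_deg)) < 1e-3

    def test_refine_from_far_init_converges(self, model, camera, cfg):
        truth = HeadPose(5.0, 5.0, 0.0, 0.0, 0.0, 1000.0)
        obs = project(model, truth, camera)
        res = refine_pose(obs, model, camera,
                          HeadPose(0.0, 0.0, 0.0, 50.0, -50.0, 1500.0), cfg)
        assert res.tracked
        assert np.max(np.abs(res.pose.angles_deg - truth.angles_deg)) < 1e-3


class TestConfidence:
    def test_linear_mapping(self, cfg):
        assert compute_confidence(0.0, cfg) == 1.0
        assert compute_confidence(cfg.residual_scale, cfg) == 0.0
        assert compute_confidence(2 * cfg.residual_scale, cfg) == 0.0
        assert compute_confidence(cfg.residual_scale / 2, cfg) == 0.5

    def test_negative_residual_rejected(self, cfg):
        with pytest.raises(ValueError):
            compute_confidence(-0.1, cfg)

    def test_monotone_in_residual(self, cfg):
        grid = np.linspace(0, 0.2, 41)
        vals = [compute_confidence(r, cfg) for r in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_confidence_decreases_with_noise(self, model, camera_f1000, cfg):
        truth = HeadPose(10.0, 0.0, 0.0, 0.0, 0.0, 1200.0)
        means = []
        for sd in (0.5, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(13)
            confs = [estimate_pose(
                noisy_observation(model, truth, camera_f1000, sd, rng),
                model, camera_f1000, cfg).confidence for _ in range(25)]
            means.append(np.mean(confs))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestDistance:
    def test_noiseless_distance(self, model, camera, cfg):
        truth = HeadPose(0.0, 0.0, 0.0, 0.0, 0.0, 1200.0)
        res = estimate_pose(project(model, truth, camera), model, camera, cfg)
        assert abs(estimate_distance(res) - 1200.0) < 0.1

    def test_wrong_assumed_ipd_biases_distance(self, camera, cfg):
        # subject with a true 70 mm IPD fitted with the 65 mm model:
        # distance comes back scaled by ~65/70
        subject = make_subject(seed=0, shape_sd_mm=0.0, ipd_mm=70.0)
        truth = HeadPose(0.0, 0.0, 0.0, 0.0, 0.0, 1200.0)
        obs = project(subject.model, truth, camera)
        res = estimate_pose(obs, camera=camera, cfg=cfg)
        assert res.tracked
        expected = 1200.0 * 65.0 / 70.0
        assert abs(estimate_distance(res) - expected) / expected < 0.01

    def test_untracked_distance_raises(self, model, camera, cfg):
        obs = LandmarkObservation(0, np.full((68, 2), np.nan),
                                  np.zeros(68, dtype=bool))
        res = estimate_pose(obs, model, camera, cfg)
        with pytest.raises(NotTrackedError):
            estimate_distance(res)


class TestModelResultsSurface:
    def test_model_fit_matches_function(self, model, camera, cfg):
        truth = HeadPose(12.0, -6.0, 4.0, 10.0, -20.0, 1300.0)
        obs = project(model, truth, camera)
        res_fn = estimate_pose(obs, model, camera, cfg)
        res_m = LandmarkPoseModel(obs, model, camera, cfg).fit()
        assert np.allclose(res_m.pose.angles_deg, res_fn.pose.angles_deg)
        assert res_m.tracked and res_fn.tracked

    def test_summary_mentions_key_quantities(self, model, camera):
        truth = HeadPose(12.0, -6.0, 4.0, 0.0, 0.0, 1300.0)
        res = LandmarkPoseModel(project(model, truth, camera),
                                model, camera).fit()
        text = res.summary()
        for token in ("yaw", "pitch", "roll", "confidence", "distance"):
            assert token in text

    def test_from_dataframe_round_trip(self, model, camera, cfg):
        import pandas as pd

        truth = HeadPose(8.0, 3.0, -2.0, 0.0, 0.0, 1200.0)
        obs = project(model, truth, camera, frame_id=4)
        rows = [(4, i, obs.points_px[i, 0], obs.points_px[i, 1], 1)
                for i in range(68)]
        df = pd.DataFrame(rows, columns=["frame_id", "landmark_index",
                                         "u_px", "v_px", "visible"])
        res = LandmarkPoseModel.from_dataframe(
            df, frame_id=4, face_model=model, camera=camera, config=cfg).fit()
        assert np.max(np.abs(res.pose.angles_deg - truth.angles_deg)) < 1e-3
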
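"""End-to-end checks on rendered frames: detector vs renderer ground truth,
identification correctness, tracking drift and the evaluation metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyltrack.camera import Pose
from cyltrack.dots import detect_dots
from cyltrack.evaluation import (detection_success, relative_pose_error,
                                 run_workspace_sweep, summarize_records)
from cyltrack.identification import identify_frame
from cyltrack.pipeline import MarkerTracker
from cyltrack.scene import RenderConfig, marker_pose, render_cylinder_frame
from cyltrack.tracking import TrackMode

# a mixed battery of views covering all three patterns, the working
# depth range and rotations about each axis
POSE_BATTERY = [
    dict(distance=100, face_offset_deg=25),
    dict(distance=60, face_offset_deg=0),
    dict(distance=150, face_offset_deg=25),
    dict(distance=100, face_offset_deg=-115),          # top pattern
    dict(distance=100, face_offset_deg=115),           # bottom pattern
    dict(distance=80, roll=20),
    dict(distance=80, pitch=25),
    dict(distance=80, yaw=30),
    dict(distance=120, roll=10, pitch=-15, yaw=20, face_offset_deg=25),
]


class TestDetectorAgainstRenderer:
    @pytest.mark.parametrize("kwargs", POSE_BATTERY)
    def test_noise_free_candidates_match_visible_dots(self, spec, camera,
                                                      kwargs):
        pose = marker_pose(spec, **kwargs)
        img, gt = render_cylinder_frame(spec, camera, pose, RenderConfig())
        cands = detect_dots(img)
        vis = gt.visible_dot_ids()
        assert len(cands) == vis.size
        # every candidate lies within 0.5 px of an exact projection
        for c in cands:
            d = np.linalg.norm(gt.dot_proj[vis] - c.centre, axis=1).min()
            assert d < 0.5

    @pytest.mark.parametrize("kwargs", POSE_BATTERY)
    def test_identities_match_ground_truth(self, spec, camera, model, kwargs):
        pose = marker_pose(spec, **kwargs)
        cfg = RenderConfig(noise_sigma=2.0, blur_sigma=0.5, seed=11)
        img, gt = render_cylinder_frame(spec, camera, pose, cfg)
        fd = identify_frame(img, spec, model)
        assert fd.status == "identified"
        for p in fd.patterns.values():
            for mid, pt in zip(p.dot_ids, p.image_points):
                err = np.linalg.norm(gt.dot_proj[mid] - pt)
                assert np.isfinite(err) and err < 2.0, \
                    f"dot {mid} misassigned by {err:.2f} px"
        if fd.vertex_ids is not None:
            for vid, pt in zip(fd.vertex_ids, fd.vertex_points):
                err = np.linalg.norm(gt.vertex_proj[vid] - pt)
                assert np.isfinite(err) and err < 2.5

    def test_emitted_vertices_near_truth(self, spec, camera, model):
        pose = marker_pose(spec, 80.0, face_offset_deg=25)
        cfg = RenderConfig(noise_sigma=2.0, blur_sigma=0.5, seed=4)
        img, gt = render_cylinder_frame(spec, camera, pose, cfg)
        fd = identify_frame(img, spec, model)
        assert fd.vertex_ids is not None and len(fd.vertex_ids) >= 2
        for vid, pt in zip(fd.vertex_ids, fd.vertex_points):
            assert np.linalg.norm(gt.vertex_proj[vid] - pt) < 1.5

    def test_classification_stable_under_in_plane_rotation(self, spec,
                                                           camera, model):
        for yaw in (-10, -5, 0, 5, 10):
            pose = marker_pose(spec, 90.0, yaw=yaw, face_offset_deg=115)
            img, _ = render_cylinder_frame(spec, camera, pose, RenderConfig())
            fd = identify_frame(img, spec, model)
            assert list(fd.patterns) == ["bottom"]


class TestFlowDrift:
    def test_drift_bounded_over_slow_translation(self, spec, camera, model):
        # 30 flow-tracked frames at <= 2 px/frame: recovered dot
        # positions stay within 3 px of the exact projections
        tracker = MarkerTracker(spec, camera)
        base = RenderConfig(noise_sigma=1.0, blur_sigma=0.5, seed=9)
        offsets = np.linspace(0, 5.0, 31)    # mm; about 1.7 px/frame
        first = True
        for i, off in enumerate(offsets):
            pose = marker_pose(spec, 90.0, offset=(off, 0.3 * off),
                               face_offset_deg=25)
            img, gt = render_cylinder_frame(spec, camera, pose, base,
                                            frame_index=i)
            if first:
                res = tracker.process(img)
                assert res.mode is TrackMode.DETECTED
                first = False
                continue
            # force the temporal path by withholding detection
            from cyltrack.tracking import step

            st = step(tracker.state, np.asarray(img, dtype=float), None,
                      flow_cfg=tracker.flow_config, seed=0)
            assert st.mode is TrackMode.FLOW_TRACKING
            for mid, pt, measured in zip(st.ids, st.image_points,
                                         st.tracked_mask):
                if np.isfinite(gt.dot_proj[mid]).all():
                    assert np.linalg.norm(pt - gt.dot_proj[mid]) < 3.0


class TestEvaluationMetrics:
    def test_relative_pose_error_cases(self):
        p = Pose(Rotation.from_euler("z", 30, degrees=True).as_matrix(),
                 np.array([10.0, 20.0, 100.0]))
        assert relative_pose_error(p, p) == (0.0, 0.0)
        # translation offset expressed in the truth frame keeps the norm
        shifted = Pose(p.rotation, p.translation + p.rotation @ [3.0, 4.0, 0])
        t, r = relative_pose_error(shifted, p)
        assert (t, r) == pytest.approx((5.0, 0.0), abs=1e-9)
        rotated = Pose(p.rotation @ Rotation.from_euler(
            "z", 10, degrees=True).as_matrix(), p.translation)
        t, r = relative_pose_error(rotated, p)
        assert (t, r) == pytest.approx((0.0, 10.0), abs=1e-9)

    def test_relative_pose_error_symmetric(self, rng):
        a = Pose(Rotation.random(random_state=1).as_matrix(),
                 rng.normal(0, 10, 3))
        b = Pose(Rotation.random(random_state=2).as_matrix(),
                 rng.normal(0, 10, 3))
        assert relative_pose_error(a, b)[1] == pytest.approx(
            relative_pose_error(b, a)[1])

    def test_detection_success_rules(self, spec, camera, model):
        pose = marker_pose(spec, 80.0)
        cfg = RenderConfig(noise_sigma=2.0, blur_sigma=0.5, seed=2)
        img, _ = render_cylinder_frame(spec, camera, pose, cfg)
        tracker = MarkerTracker(spec, camera)
        res = tracker.process(img)
        n_dots = len(model.dots)
        # a frame with an identified pattern satisfies the hybrid-dots rule
        assert detection_success(res, "hybrid_dots")
        # hybrid chessboard needs >= 4 same-orientation vertices
        labels = [v.orientation_label for v in res.detection.vertices]
        _, counts = np.unique(labels, return_counts=True)
        assert detection_success(res, "hybrid_chessboard") == \
            (counts.max() >= 4)
        # the dot-only rule requires every single dot visible: a single
        # pattern in view fails it
        assert not detection_success(res, "dot_only", n_dots)
        with pytest.raises(ValueError):
            detection_success(res, "nonsense")

    def test_hybrid_dots_implied_by_full_identification(self, spec, camera):
        # consistency: whenever all three patterns are identified the
        # hybrid-dots rule must hold
        pose = marker_pose(spec, 100.0)
        img, _ = render_cylinder_frame(
            spec, camera, pose, RenderConfig(noise_sigma=2.0, seed=3))
        tracker = MarkerTracker(spec, camera)
        res = tracker.process(img)
        if len(res.detection.patterns) == 3:
            assert detection_success(res, "hybrid_dots")
        assert detection_success(res, "hybrid_dots") or \
            len(res.detection.patterns) == 0


class TestWorkspaceSweep:
    def test_depth_sweep_full_detection_in_working_range(self, spec, camera):
        cfg = RenderConfig(noise_sigma=1.0, blur_sigma=0.5, seed=6)
        table = run_workspace_sweep(spec, camera, "depth",
                                    [60.0, 100.0, 140.0], cfg=cfg)
        assert (table["detection_rate"] == 1.0).all()
        assert (table["translation_mean"] < 1.0).all()

    def test_roll_sweep_symmetric_rates(self, spec, camera):
        cfg = RenderConfig(noise_sigma=1.0, blur_sigma=0.5, seed=6)
        table = run_workspace_sweep(spec, camera, "roll",
                                    [-25.0, 0.0, 25.0], distance=90.0,
                                    cfg=cfg)
        rates = table["detection_rate"].to_numpy()
        assert rates[0] == rates[2]
        assert rates[1] == 1.0

    def test_invalid_axis(self, spec, camera):
        with pytest.raises(ValueError):
            run_workspace_sweep(spec, camera, "twist", [1.0])
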
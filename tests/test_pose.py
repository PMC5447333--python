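"""Two-solution planar pose estimation and ambiguity resolution."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyltrack.camera import CameraIntrinsics, Pose, project_points
from cyltrack.geometry import build_model_points
from cyltrack.pose import (InsufficientConstraintError, PoseCandidate,
                           detect_ambiguity, estimate_pose_candidates,
                           refine_pose, reprojection_error, resolve_pose)


def make_pose(rx=0.0, ry=0.0, rz=0.0, t=(0.0, 0.0, 100.0)):
    R = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
    return Pose(R, np.array(t))


@pytest.fixture(scope="module")
def pattern_points(spec=None):
    from cyltrack import MarkerSpec

    model = build_model_points(MarkerSpec())
    ids = model.pattern_dot_ids("middle")
    return model.dot_xyz(ids)


class TestReprojectionError:
    def test_exact_pose_zero_error(self, camera, pattern_points):
        pose = make_pose(rz=10, ry=5)
        uv = project_points(camera, pose, pattern_points)
        assert reprojection_error(pose, camera, pattern_points, uv) < 1e-6

    def test_lateral_offset_scales_with_focal_over_depth(self, camera):
        pts = np.array([[0.0, 0.0, 0.0], [5, 0, 0], [0, 5, 0], [5, 5, 0]])
        pose = make_pose(t=(0, 0, 100))
        uv = project_points(camera, pose, pts)
        shifted = Pose(pose.rotation, pose.translation + [1.0, 0, 0])
        err = reprojection_error(shifted, camera, pts, uv)
        assert err == pytest.approx(camera.fx * 1.0 / 100.0, rel=0.02)

    def test_empty_correspondences(self, camera):
        with pytest.raises(ValueError):
            reprojection_error(make_pose(), camera, np.zeros((0, 3)),
                               np.zeros((0, 2)))


class TestCandidates:
    def test_strong_perspective_unambiguous(self, camera, pattern_points):
        # close and slanted: the correct solution clearly wins
        pose = make_pose(rx=35, t=(0, 0, 55))
        uv = project_points(camera, pose, pattern_points)
        c1, c2 = estimate_pose_candidates(camera, pattern_points, uv)
        assert c1.mean_reprojection_error < 0.05
        assert c2.mean_reprojection_error / max(c1.mean_reprojection_error,
                                                1e-9) > 3.0
        dt = np.linalg.norm(c1.pose.translation - pose.translation)
        dr = np.degrees(np.linalg.norm(Rotation.from_matrix(
            c1.pose.rotation.T @ pose.rotation).as_rotvec()))
        assert dt < 2.0 and dr < 1.0

    def test_near_affine_produces_reflection_pair(self, camera, pattern_points):
        # far and small: both candidates explain the dots almost equally
        pose = make_pose(rx=10, t=(0, 0, 300))
        uv = project_points(camera, pose, pattern_points)
        c1, c2 = estimate_pose_candidates(camera, pattern_points, uv)
        assert c1.mean_reprojection_error < 0.5
        assert c2.mean_reprojection_error < 0.5
        # one matches the truth, the other is its plane reflection
        errs = []
        for c in (c1, c2):
            errs.append(np.degrees(np.linalg.norm(Rotation.from_matrix(
                c.pose.rotation.T @ pose.rotation).as_rotvec())))
        assert min(errs) < 1.0
        assert max(errs) > 10.0

    def test_three_points_raise(self, camera):
        with pytest.raises(InsufficientConstraintError):
            estimate_pose_candidates(camera, np.zeros((3, 3)), np.zeros((3, 2)))

    def test_collinear_points_raise(self, camera):
        pts = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        uv = np.stack([np.arange(5.0) * 10 + 400, np.full(5, 270.0)], axis=1)
        with pytest.raises(InsufficientConstraintError):
            estimate_pose_candidates(camera, pts, uv)


class TestAmbiguityRule:
    def _cand(self, err):
        return PoseCandidate(make_pose(), err, "solution_1")

    def test_both_near_zero_is_ambiguous(self):
        assert detect_ambiguity(self._cand(0.3), self._cand(0.4))

    def test_clear_winner_not_ambiguous(self):
        assert not detect_ambiguity(self._cand(0.5), self._cand(6.0))

    def test_similar_but_large_errors_not_ambiguous(self):
        # neither error is close to zero: falls through to the
        # lowest-error choice without the ambiguity branch
        assert not detect_ambiguity(self._cand(3.9), self._cand(4.1),
                                    abs_threshold=2.0)


class TestResolve:
    def _scene(self, camera, depth=300.0, rx=10.0, jitter=0.1, seed=5):
        # small zero-mean jitter mimics real centroid noise; without it
        # the true solution's error is ~1e-14 px and the ambiguity rule
        # cannot trigger on exact synthetic data
        from cyltrack import MarkerSpec

        rng = np.random.default_rng(seed)
        model = build_model_points(MarkerSpec())
        ids = model.pattern_dot_ids("middle")
        dots = model.dot_xyz(ids)
        vids = model.row_vertex_ids("middle")
        verts = model.vertex_xyz(vids)
        pose = make_pose(rx=rx, t=(0, 0, depth))
        duv = project_points(camera, pose, dots) + rng.normal(0, jitter, (len(dots), 2))
        vuv = project_points(camera, pose, verts) + rng.normal(0, jitter, (len(verts), 2))
        return pose, dots, duv, verts, vuv

    def test_non_ambiguous_takes_lower_error(self, camera):
        pose, dots, duv, _, _ = self._scene(camera, depth=55, rx=35,
                                            jitter=0.0)
        cands = estimate_pose_candidates(camera, dots, duv)
        resolved, diag = resolve_pose(cands, camera, refine=False)
        assert not diag["ambiguous"]
        assert diag["source"] == "solution_1"

    def test_vertices_resolve_ambiguity(self, camera):
        pose, dots, duv, verts, vuv = self._scene(camera)
        cands = estimate_pose_candidates(camera, dots, duv)
        resolved, diag = resolve_pose(cands, camera, verts, vuv, refine=False)
        assert diag["resolved_by"] == "vertices"
        ve = diag["vertex_errors"]
        dr = np.degrees(np.linalg.norm(Rotation.from_matrix(
            resolved.rotation.T @ pose.rotation).as_rotvec()))
        # the true branch was chosen (the reflection lies ~46 deg away)
        assert dr < 5.0
        # the wrong candidate's vertex error strictly exceeds the correct one
        assert max(ve) > 3 * min(ve)

    def test_ambiguous_without_vertices_flagged(self, camera):
        pose, dots, duv, _, _ = self._scene(camera)
        cands = estimate_pose_candidates(camera, dots, duv)
        _, diag = resolve_pose(cands, camera, refine=False)
        assert diag["ambiguous"] and diag["unresolved"]

    def test_prior_pose_breaks_tie(self, camera):
        pose, dots, duv, _, _ = self._scene(camera)
        cands = estimate_pose_candidates(camera, dots, duv)
        resolved, diag = resolve_pose(cands, camera, prior_pose=pose,
                                      refine=False)
        assert diag["resolved_by"] == "prior"
        dr = np.degrees(np.linalg.norm(Rotation.from_matrix(
            resolved.rotation.T @ pose.rotation).as_rotvec()))
        assert dr < 5.0

    def test_jitter_degrades_gracefully(self, camera, rng):
        # zero-mean 0.3 px jitter: error grows continuously, the resolved
        # branch never flips to the reflection
        pose, dots, duv, verts, vuv = self._scene(camera, depth=150,
                                                  jitter=0.0)
        errs = []
        for sigma in (0.0, 0.1, 0.2, 0.3):
            noisy = duv + rng.normal(0, sigma, duv.shape)
            cands = estimate_pose_candidates(camera, dots, noisy)
            resolved, _ = resolve_pose(cands, camera, verts, vuv, refine=False)
            dr = np.degrees(np.linalg.norm(Rotation.from_matrix(
                resolved.rotation.T @ pose.rotation).as_rotvec()))
            errs.append(dr)
            assert dr < 10.0    # never the ~20 degree reflection flip
        assert errs[0] < 0.1


class TestRefine:
    def test_refinement_recovers_perturbed_pose(self, camera, pattern_points):
        pose = make_pose(rx=20, rz=5, t=(2, -3, 90))
        uv = project_points(camera, pose, pattern_points)
        rough = Pose(Rotation.from_euler("x", 22, degrees=True).as_matrix()
                     @ Rotation.from_euler("z", 5, degrees=True).as_matrix(),
                     pose.translation + [0.5, 0.5, 2.0])
        out = refine_pose(rough, camera, pattern_points, uv)
        assert reprojection_error(out, camera, pattern_points, uv) < 1e-6
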
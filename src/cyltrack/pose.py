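"""Pose estimation from identified features, with ambiguity resolution.

A single two-row dot pattern is planar, and planar targets under weak
perspective admit two pose solutions related by a reflection of the model
plane about a plane through the line of sight: both align the dot
projections almost equally well.  This module computes *both* candidates
(homography decomposition for the first; the second is constructed by
flipping the rotation's middle ZYZ Euler angle in the frame whose z axis
points along the translation, then both are polished by Gauss-Newton).
When the two reprojection errors are both small and similar, the pose is
flagged ambiguous and resolved using the chessboard vertices: they live
on the cylinder surface off the dot-pattern plane, so the wrong candidate
projects them far from their detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .camera import CameraIntrinsics, Pose

__all__ = [
    "PoseCandidate",
    "InsufficientConstraintError",
    "reprojection_error",
    "estimate_pose_candidates",
    "detect_ambiguity",
    "resolve_pose",
    "refine_pose",
]


class InsufficientConstraintError(ValueError):
    """Fewer than four correspondences, or a degenerate configuration."""


@dataclass
class PoseCandidate:
    pose: Pose
    mean_reprojection_error: float
    source: str                  # solution_1 / solution_2


def _project_safe(K: CameraIntrinsics, pose: Pose, pts: np.ndarray) -> np.ndarray:
    """Projection that returns +inf rows for non-positive depths."""
    cam = pose.apply(pts)
    uv = np.full((len(pts), 2), np.inf)
    ok = cam[:, 2] > 1e-9
    if np.any(ok):
        xy = cam[ok, :2] / cam[ok, 2:3]
        uv[ok] = K.normalized_to_pixels(xy)
    return uv


def reprojection_error(pose: Pose, K: CameraIntrinsics,
                       model_points, image_points) -> float:
    """Mean Euclidean pixel distance between projections and detections."""
    mp = np.atleast_2d(np.asarray(model_points, dtype=float))
    ip = np.atleast_2d(np.asarray(image_points, dtype=float))
    if len(mp) == 0 or len(mp) != len(ip):
        raise ValueError("need equally many (and at least one) correspondences")
    uv = _project_safe(K, pose, mp)
    return float(np.mean(np.linalg.norm(uv - ip, axis=1)))


def _polygon_centroids(uv: np.ndarray) -> np.ndarray:
    """Area centroids of closed polygons, ``(n, k, 2) -> (n, 2)``."""
    x, y = uv[..., 0], uv[..., 1]
    xn, yn = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    cross = x * yn - xn * y
    a = cross.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = ((x + xn) * cross).sum(axis=-1) / (3.0 * a)
        cy = ((y + yn) * cross).sum(axis=-1) / (3.0 * a)
    out = np.stack([cx, cy], axis=-1)
    bad = ~np.isfinite(out).all(axis=-1)
    out[bad] = uv[bad].mean(axis=-2)
    return out


def refine_pose(pose: Pose, K: CameraIntrinsics, model_points,
                image_points, dot_boundaries=None,
                boundary_observations=None) -> Pose:
    """Levenberg-Marquardt reprojection refinement.

    ``model_points`` / ``image_points`` are point correspondences
    (vertices, or dots treated as points).  ``dot_boundaries`` optionally
    carries ``(n, k, 3)`` boundary rings of curved dots whose predicted
    measurement is the centroid of the projected ring, matching what the
    blob detector actually measures; ``boundary_observations`` are the
    corresponding detected centroids.
    """
    mp = np.asarray(model_points, dtype=float).reshape(-1, 3)
    ip = np.asarray(image_points, dtype=float).reshape(-1, 2)
    if dot_boundaries is not None:
        db = np.asarray(dot_boundaries, dtype=float)
        bo = np.asarray(boundary_observations, dtype=float)
    else:
        db = bo = None

    def resid(x):
        p = Pose.from_rotvec(x[:3], x[3:])
        parts = []
        if len(mp):
            parts.append((_project_safe(K, p, mp) - ip).ravel())
        if db is not None:
            flat = _project_safe(K, p, db.reshape(-1, 3)).reshape(db.shape[0], -1, 2)
            parts.append((_polygon_centroids(flat) - bo).ravel())
        r = np.concatenate(parts)
        return np.where(np.isfinite(r), r, 1e6)

    x0 = np.concatenate([pose.rotvec(), pose.translation])
    sol = least_squares(resid, x0, method="lm", max_nfev=200)
    return Pose.from_rotvec(sol.x[:3], sol.x[3:])


def _plane_frame(points: np.ndarray):
    """Least-squares plane through coplanar-ish 3D points: returns the
    centroid, an orthonormal in-plane basis and the max out-of-plane
    deviation (for diagnostics; exactly 0 for a single two-row pattern)."""
    c = points.mean(axis=0)
    Q = points - c
    _, sv, Vt = np.linalg.svd(Q, full_matrices=False)
    e1, e2, n = Vt[0], Vt[1], Vt[2]
    if np.linalg.det(np.stack([e1, e2, n])) < 0:
        n = -n
    dev = float(np.abs(Q @ n).max())
    return c, np.stack([e1, e2, n], axis=1), dev, sv


def _pose_from_homography(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zhang-style decomposition of a plane(mm)->normalized-image
    homography into an (orthonormalised) rotation and translation."""
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 2.0 / max(np.linalg.norm(h1) + np.linalg.norm(h2), 1e-12)
    if h3[2] * lam < 0:
        lam = -lam
    r1, r2 = lam * h1, lam * h2
    Rm = np.stack([r1, r2, np.cross(r1, r2)], axis=1)
    U, _, Vt = np.linalg.svd(Rm)
    Rm = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return Rm, lam * h3


def _flip_candidate(Rm: np.ndarray, t: np.ndarray) -> np.ndarray:
    """The reflection-related alternative rotation: in the rotated frame
    whose z axis runs along the translation, negate the middle ZYZ Euler
    angle (the plane tilt); translation is kept as the starting value."""
    tz = t / max(np.linalg.norm(t), 1e-12)
    Rv = Rotation.align_vectors([[0.0, 0.0, 1.0]], [tz])[0].as_matrix()
    a, b, c = Rotation.from_matrix(Rv @ Rm).as_euler("ZYZ")
    R2 = Rotation.from_euler("ZYZ", [a, -b, c]).as_matrix()
    return Rv.T @ R2


def estimate_pose_candidates(K: CameraIntrinsics, model_points, image_points
                             ) -> tuple[PoseCandidate, PoseCandidate]:
    """Both planar-pose solutions for one (near-)planar correspondence set.

    The model points are orthogonally projected onto their least-squares
    plane, a plane-to-image homography seeds the first solution, the
    ZYZ-flip construction seeds the second, and each is refined by
    minimising the pixel reprojection error.  Candidates are returned
    ordered by their mean reprojection error.
    """
    mp = np.atleast_2d(np.asarray(model_points, dtype=float))
    ip = np.atleast_2d(np.asarray(image_points, dtype=float))
    if len(mp) < 4:
        raise InsufficientConstraintError("at least four dots are required")
    c, B, dev, sv = _plane_frame(mp)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise InsufficientConstraintError("model dots are collinear")
    plane_xy = (mp - c) @ B[:, :2]
    q = K.pixels_to_normalized(ip)
    from .tracking import DegenerateGeometryError, estimate_homography

    try:
        H, _ = estimate_homography(plane_xy, q)
    except DegenerateGeometryError as exc:
        raise InsufficientConstraintError(str(exc)) from None
    R_pl, t_pl = _pose_from_homography(H)

    def compose(R_pl, t_pl) -> Pose:
        return Pose(R_pl @ B.T, t_pl - R_pl @ B.T @ c)

    pose1 = refine_pose(compose(R_pl, t_pl), K, mp, ip)
    c1 = PoseCandidate(pose1, reprojection_error(pose1, K, mp, ip),
                       "solution_1")
    flip = compose(_flip_candidate(R_pl, t_pl), t_pl)
    pose2 = refine_pose(flip, K, mp, ip)
    rot_gap = np.degrees(np.linalg.norm(Rotation.from_matrix(
        pose1.rotation.T @ pose2.rotation).as_rotvec()))
    if rot_gap < 2.0:
        # under strong perspective the second local minimum does not
        # exist and refinement collapses onto the first solution; the
        # alternative is then the raw reflection with its (large) error
        pose2 = flip
    c2 = PoseCandidate(pose2, reprojection_error(pose2, K, mp, ip),
                       "solution_2")
    if c2.mean_reprojection_error < c1.mean_reprojection_error:
        c1, c2 = (PoseCandidate(c2.pose, c2.mean_reprojection_error,
                                "solution_1"),
                  PoseCandidate(c1.pose, c1.mean_reprojection_error,
                                "solution_2"))
    return c1, c2


def detect_ambiguity(candidate_1: PoseCandidate, candidate_2: PoseCandidate,
                     abs_threshold: float = 2.0,
                     ratio_threshold: float = 1.5) -> bool:
    """Ambiguous iff both reprojection errors are close to zero (below
    ``abs_threshold`` px) *and* neither clearly wins (error ratio below
    ``ratio_threshold``)."""
    e = sorted([candidate_1.mean_reprojection_error,
                candidate_2.mean_reprojection_error])
    if e[1] >= abs_threshold:
        return False
    return e[1] / max(e[0], 1e-9) < ratio_threshold


def resolve_pose(candidates, K: CameraIntrinsics,
                 vertex_model_points=None, vertex_image_points=None,
                 prior_pose: Pose | None = None,
                 refine: bool = True,
                 refine_model_points=None, refine_image_points=None,
                 refine_dot_boundaries=None, refine_dot_observations=None,
                 abs_threshold: float = 2.0, ratio_threshold: float = 1.5,
                 ) -> tuple[Pose, dict]:
    """Pick the correct candidate and optionally refine it.

    Non-ambiguous cases take the lower-error candidate.  Ambiguous cases
    are decided by the vertex reprojection error (the vertices lie off
    the dot plane, so the reflected solution projects them far away);
    with no vertices available, a prior pose breaks the tie, else the
    lower-error candidate is kept and flagged unresolved.
    """
    c1, c2 = candidates
    diag = {
        "ambiguous": detect_ambiguity(c1, c2, abs_threshold, ratio_threshold),
        "resolved_by": "reprojection",
        "unresolved": False,
        "dot_errors": (c1.mean_reprojection_error, c2.mean_reprojection_error),
        "vertex_errors": None,
    }
    chosen = c1 if c1.mean_reprojection_error <= c2.mean_reprojection_error else c2
    has_verts = (vertex_model_points is not None
                 and len(np.atleast_2d(vertex_model_points)) > 0)
    if diag["ambiguous"]:
        if has_verts:
            vm = np.atleast_2d(np.asarray(vertex_model_points, dtype=float))
            vi = np.atleast_2d(np.asarray(vertex_image_points, dtype=float))
            ve = [reprojection_error(cd.pose, K, vm, vi) for cd in (c1, c2)]
            diag["vertex_errors"] = tuple(ve)
            chosen = (c1, c2)[int(np.argmin(ve))]
            diag["resolved_by"] = "vertices"
        elif prior_pose is not None:
            dr = [np.linalg.norm(Rotation.from_matrix(
                prior_pose.rotation.T @ cd.pose.rotation).as_rotvec())
                for cd in (c1, c2)]
            chosen = (c1, c2)[int(np.argmin(dr))]
            diag["resolved_by"] = "prior"
        else:
            diag["unresolved"] = True
    pose = chosen.pose
    diag["source"] = chosen.source
    if refine:
        mp = refine_model_points if refine_model_points is not None \
            else np.zeros((0, 3))
        ip = refine_image_points if refine_image_points is not None \
            else np.zeros((0, 2))
        n_pts = len(np.atleast_2d(mp)) if len(np.atleast_2d(mp)) else 0
        n_dots = 0 if refine_dot_boundaries is None else len(refine_dot_boundaries)
        if n_pts + n_dots >= 4:
            pose = refine_pose(pose, K, mp, ip,
                               refine_dot_boundaries, refine_dot_observations)
    return pose, diag
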
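"""Synthetic renderer: the marker wrapped on a cylinder under a pinhole camera.

This module is the package's test bench.  It renders the printed pattern
mapped onto the cylinder surface at a known rigid pose, applies controlled
degradations (blur, illumination gain, additive Gaussian noise, polygonal
occluders emulating blood stains) and reports exact ground truth: the pose,
per-feature visibility and the exact projected feature centres.  Rendering
is done by inverse mapping — a per-pixel ray/cylinder intersection followed
by a bilinear texture lookup — which gives exact silhouettes with no holes
at grazing angles.

All randomness flows through the single seed in :class:`RenderConfig`; the
same seed renders byte-identical frames.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .camera import CameraIntrinsics, Pose, project_points, rot_x, rot_y, rot_z
from .geometry import (MarkerSpec, ModelPointSet, build_model_points,
                       map_marker_to_cylinder, render_marker_raster,
                       surface_normal)

__all__ = [
    "RenderConfig",
    "FrameGroundTruth",
    "render_cylinder_frame",
    "generate_sequence",
    "marker_pose",
    "rotational_trajectory",
    "depth_sweep_trajectory",
]


@dataclass(frozen=True)
class RenderConfig:
    """Degradation and appearance settings for the synthetic camera."""

    background: float = 120.0       # uniform tissue-grey backdrop
    body_level: float = 235.0       # unprinted (white) cylinder surface
    ink_level: float = 25.0         # printed feature intensity
    occluder_level: float = 45.0    # the fake-blood stain intensity
    noise_sigma: float = 0.0        # additive Gaussian noise, grey levels
    blur_sigma: float = 0.0         # Gaussian blur, px
    illumination_gain: float = 1.0  # multiplicative gain applied before noise
    occlusion_masks: tuple = ()     # image-space polygons, each (N, 2) px
    seed: int = 0
    texture_resolution: float = 10.0   # px/mm of the wrapped print
    body_margin: float = 4.0           # bare cylinder beyond the pattern, mm
    max_incidence_deg: float = 60.0    # ground-truth visibility cut-off
    visibility_margin_px: float = 6.0  # border margin for "in image"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be >= 0")


@dataclass
class FrameGroundTruth:
    """Exact per-frame truth written by the renderer."""

    pose: Pose
    dot_visible: np.ndarray      # (n_dots,) bool
    dot_proj: np.ndarray         # (n_dots, 2) px (NaN when behind camera)
    vertex_visible: np.ndarray
    vertex_proj: np.ndarray
    frame_index: int = 0

    def visible_dot_ids(self) -> np.ndarray:
        return np.nonzero(self.dot_visible)[0]

    def visible_vertex_ids(self) -> np.ndarray:
        return np.nonzero(self.vertex_visible)[0]

    def to_json(self) -> str:
        rec = {
            "frame": int(self.frame_index),
            "pose": [float(v) for v in self.pose.matrix().ravel()],
            "visible_dots": [int(i) for i in self.visible_dot_ids()],
            "visible_vertices": [int(i) for i in self.visible_vertex_ids()],
            "dot_proj": np.where(np.isfinite(self.dot_proj),
                                 self.dot_proj, None).tolist(),
            "vertex_proj": np.where(np.isfinite(self.vertex_proj),
                                    self.vertex_proj, None).tolist(),
        }
        return json.dumps(rec)


# -- cached expensive pieces ------------------------------------------------

@functools.lru_cache(maxsize=8)
def _texture(spec: MarkerSpec, resolution: float) -> np.ndarray:
    return render_marker_raster(spec, resolution).astype(float)


@functools.lru_cache(maxsize=8)
def _pixel_rays(K: CameraIntrinsics) -> np.ndarray:
    """Normalized-plane ray directions for every pixel centre, (H, W, 2)."""
    w, h = K.image_size
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    uv = np.stack([u, v], axis=-1)
    return K.pixels_to_normalized(uv.reshape(-1, 2)).reshape(h, w, 2)


@functools.lru_cache(maxsize=8)
def _model(spec: MarkerSpec) -> ModelPointSet:
    return build_model_points(spec)


def _point_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorised over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < xint)
    return inside


def _fill_polygon(img: np.ndarray, poly: np.ndarray, value: float) -> None:
    from skimage.draw import polygon as sk_polygon

    rr, cc = sk_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
    img[rr, cc] = value


# -- frame rendering --------------------------------------------------------

def render_cylinder_frame(spec: MarkerSpec, K: CameraIntrinsics, pose: Pose,
                          cfg: RenderConfig | None = None,
                          frame_index: int = 0,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[np.ndarray, FrameGroundTruth]:
    """Render one frame and its exact ground truth.

    A surface feature counts as *visible* when its outward normal faces the
    camera within ``cfg.max_incidence_deg``, it projects inside the image
    (with a small border margin) and falls outside every occlusion polygon.
    Degradations are applied in the order blur, illumination, noise.
    """
    cfg = cfg or RenderConfig()
    R = spec.cylinder_radius
    tex = _texture(spec, cfg.texture_resolution)
    rays = _pixel_rays(K)
    h, w = rays.shape[:2]

    # rays and camera centre in the marker-local frame
    Rm, t = pose.rotation, pose.translation
    o = -Rm.T @ t
    d = np.concatenate([rays, np.ones((h, w, 1))], axis=-1).reshape(-1, 3) @ Rm

    dy, dz = d[:, 1], d[:, 2]
    a = dy * dy + dz * dz
    b = 2.0 * (o[1] * dy + (o[2] - R) * dz)
    c = o[1] ** 2 + (o[2] - R) ** 2 - R * R
    disc = b * b - 4.0 * a * c
    hit = disc >= 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tnear = (-b - sq) / (2.0 * a)
    hit &= tnear > 1e-9

    P = o[None, :] + tnear[:, None] * d
    X = P[:, 0]
    s_arc = R * np.mod(np.arctan2(P[:, 1], R - P[:, 2]), 2.0 * math.pi)

    on_body = hit & (X >= -cfg.body_margin) & (X <= spec.pattern_length + cfg.body_margin)
    img = np.full(h * w, float(cfg.background))
    img[on_body] = cfg.body_level

    in_pat = on_body & (X >= 0) & (X <= spec.pattern_length) & (s_arc <= spec.pattern_arc)
    if np.any(in_pat):
        res = cfg.texture_resolution
        rows = s_arc[in_pat] * res - 0.5
        cols = X[in_pat] * res - 0.5
        vals = map_coordinates(tex, np.stack([rows, cols]), order=1, mode="nearest")
        img[in_pat] = cfg.ink_level + vals / 255.0 * (cfg.body_level - cfg.ink_level)
    img = img.reshape(h, w)

    for poly in cfg.occlusion_masks:
        _fill_polygon(img, np.asarray(poly, dtype=float), cfg.occluder_level)

    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, cfg.blur_sigma)
    img = img * cfg.illumination_gain
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    gt = _ground_truth(spec, K, pose, cfg, frame_index)
    return img, gt


def _ground_truth(spec: MarkerSpec, K: CameraIntrinsics, pose: Pose,
                  cfg: RenderConfig, frame_index: int) -> FrameGroundTruth:
    model = _model(spec)
    cos_cut = math.cos(math.radians(cfg.max_incidence_deg))
    m = cfg.visibility_margin_px
    w, h = K.image_size

    def assess(xyz: np.ndarray):
        cam = pose.apply(xyz)
        depth_ok = cam[:, 2] > 0
        proj = np.full((len(xyz), 2), np.nan)
        if np.any(depth_ok):
            xy = cam[depth_ok, :2] / cam[depth_ok, 2:3]
            proj[depth_ok] = K.normalized_to_pixels(xy)
        n_cam = surface_normal(xyz, spec.cylinder_radius) @ pose.rotation.T
        view = cam / np.maximum(np.linalg.norm(cam, axis=1, keepdims=True), 1e-12)
        facing = -np.einsum("ij,ij->i", n_cam, view)
        vis = depth_ok & (facing >= cos_cut)
        with np.errstate(invalid="ignore"):
            vis &= (proj[:, 0] >= m) & (proj[:, 0] < w - m) \
                 & (proj[:, 1] >= m) & (proj[:, 1] < h - m)
        for poly in cfg.occlusion_masks:
            safe = np.where(np.isfinite(proj), proj, -1e6)
            vis &= ~_point_in_polygon(safe, np.asarray(poly, dtype=float))
        return vis, proj

    dv, dp = assess(model.dot_xyz())
    vv, vp = assess(model.vertex_xyz())
    return FrameGroundTruth(pose, dv, dp, vv, vp, frame_index)


def generate_sequence(spec: MarkerSpec, K: CameraIntrinsics,
                      trajectory, cfg: RenderConfig | None = None):
    """Render one frame per pose; yields ``(image, ground_truth)`` pairs.

    Per-frame noise streams are derived from the single config seed so the
    sequence is reproducible as a whole.
    """
    trajectory = list(trajectory)
    if not trajectory:
        raise ValueError("trajectory must contain at least one pose")
    cfg = cfg or RenderConfig()
    for i, pose in enumerate(trajectory):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        yield render_cylinder_frame(spec, K, pose, cfg, frame_index=i, rng=rng)


# -- canonical poses and trajectories ---------------------------------------

def marker_pose(spec: MarkerSpec, distance: float,
                roll: float = 0.0, pitch: float = 0.0, yaw: float = 0.0,
                offset: tuple[float, float] = (0.0, 0.0),
                face_offset_deg: float = 0.0) -> Pose:
    """Pose placing the marker in front of the camera.

    With all angles zero the surface point at the centre of the *middle*
    dot pattern sits on the optical axis at ``distance`` mm with its
    outward normal pointing at the camera and the cylinder axis along the
    image x direction.  ``face_offset_deg`` rotates which part of the
    circumference faces the camera.  ``roll`` / ``pitch`` / ``yaw`` (deg)
    rotate about the local axis direction, the circumferential tangent and
    the surface normal at that anchor point, in that order.
    """
    R = spec.cylinder_radius
    rows = spec.pattern_rows()
    y_face = rows[1] + 0.5 * spec.dot_row_gap \
        + math.radians(face_offset_deg) * R
    y_face = float(np.mod(y_face, 2 * math.pi * R))
    P0 = map_marker_to_cylinder(np.array([spec.pattern_length / 2.0, y_face]), R)
    n0 = surface_normal(P0, R)[0]
    ax = np.array([1.0, 0.0, 0.0])
    t0 = np.cross(n0, ax)

    B_local = np.stack([ax, t0, n0], axis=1)
    B_target = np.stack([[1, 0, 0], [0, -1, 0], [0, 0, -1]], axis=1).astype(float)
    R0 = B_target @ B_local.T

    def axis_rot(axis, deg):
        from scipy.spatial.transform import Rotation
        return Rotation.from_rotvec(np.asarray(axis) * math.radians(deg)).as_matrix()

    Rl = axis_rot(ax, roll) @ axis_rot(t0, pitch) @ axis_rot(n0, yaw)
    Rtot = R0 @ Rl
    target = np.array([offset[0], offset[1], distance])
    return Pose(Rtot, target - Rtot @ P0)


def rotational_trajectory(spec: MarkerSpec, n_frames: int,
                          depth: tuple[float, float] = (95.0, 105.0),
                          roll_amp: float = 12.0, pitch_amp: float = 15.0,
                          yaw_amp: float = 15.0,
                          face_offset_deg: float = 25.0,
                          lateral_amp: float = 3.0,
                          sequential: bool = False) -> list[Pose]:
    """Smooth parametric roll/pitch/yaw + depth sweep.

    ``sequential=True`` exercises one rotation axis at a time in three
    consecutive thirds (the detection-rate protocol); otherwise the three
    rotations are superposed sinusoids at incommensurate frequencies (the
    pose-accuracy protocol).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    poses = []
    d0, d1 = depth
    for i in range(n_frames):
        u = i / max(n_frames - 1, 1)
        z = 0.5 * (d0 + d1) + 0.5 * (d1 - d0) * math.sin(2 * math.pi * 1.3 * u)
        off = (lateral_amp * math.sin(2 * math.pi * 0.7 * u),
               lateral_amp * math.cos(2 * math.pi * 0.9 * u) * 0.5)
        if sequential:
            phase = math.sin(2 * math.pi * 1.5 * (3 * u % 1.0))
            third = int(min(3 * u, 2.999))
            roll = roll_amp * phase if third == 0 else 0.0
            pitch = pitch_amp * phase if third == 1 else 0.0
            yaw = yaw_amp * phase if third == 2 else 0.0
        else:
            roll = roll_amp * math.sin(2 * math.pi * 1.1 * u)
            pitch = pitch_amp * math.sin(2 * math.pi * 0.8 * u + 1.0)
            yaw = yaw_amp * math.sin(2 * math.pi * 0.6 * u + 2.0)
        poses.append(marker_pose(spec, z, roll=roll, pitch=pitch, yaw=yaw,
                                 offset=off, face_offset_deg=face_offset_deg))
    return poses


def depth_sweep_trajectory(spec: MarkerSpec, depths,
                           face_offset_deg: float = 0.0, **kwargs) -> list[Pose]:
    return [marker_pose(spec, float(z), face_offset_deg=face_offset_deg, **kwargs)
            for z in depths]
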
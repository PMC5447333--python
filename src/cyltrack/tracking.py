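"""Temporal tracking: sparse optical flow and homography-based recovery.

Each two-row dot pattern is exactly planar (two parallel rulings of the
cylinder), so its flat reference coordinates ``p_r`` (mm) and the image
projections ``p_m`` (px) are linked by a plane-to-plane homography,
``p_m ~ H p_r``.  When per-frame detection fails (occlusion, stains), the
previously identified dots are carried forward by pyramidal Lucas-Kanade
flow; the homography re-estimated from the surviving >= 4 points predicts
the positions of the missing dots.  When fewer than four points survive
the state degrades to *lost* and no pose is emitted until detection
recovers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "TrackMode",
    "TrackState",
    "DegenerateGeometryError",
    "estimate_homography",
    "apply_homography",
    "predict_missing",
    "track_points_flow",
    "FlowConfig",
    "step",
]


class DegenerateGeometryError(ValueError):
    """Fewer than four pairs, or a collinear configuration."""


# -- homography -------------------------------------------------------------

def _normalise(pts: np.ndarray):
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = math.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (pts - c) * s, T


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    p = pts - pts.mean(axis=0)
    sv = np.linalg.svd(p, compute_uv=False)
    return sv[1] <= tol * max(sv[0], 1.0)


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    sn, Ts = _normalise(src)
    dn, Td = _normalise(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = sn[:, 0], sn[:, 1]
    u, v = dn[:, 0], dn[:, 1]
    A[0::2, 0] = -x; A[0::2, 1] = -y; A[0::2, 2] = -1
    A[0::2, 6] = u * x; A[0::2, 7] = u * y; A[0::2, 8] = u
    A[1::2, 3] = -x; A[1::2, 4] = -y; A[1::2, 5] = -1
    A[1::2, 6] = v * x; A[1::2, 7] = v * y; A[1::2, 8] = v
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * max(sv[0], 1e-12):
        raise DegenerateGeometryError("degenerate point configuration")
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise DegenerateGeometryError("homography with vanishing scale")
    return H / H[2, 2]


def estimate_homography(ref_points, image_points, robust: bool = False,
                        seed: int = 0, inlier_px: float = 3.0,
                        n_iters: int = 200):
    """Normalised-DLT homography ``ref -> image`` (bottom-right = 1).

    With ``robust=True`` a seeded random-sampling loop scores 4-point
    hypotheses by their ``inlier_px`` consensus before the final
    least-squares fit on the inliers.  Returns ``(H, residuals)`` where
    residuals are per-point transfer errors in image units.
    """
    src = np.asarray(ref_points, dtype=float).reshape(-1, 2)
    dst = np.asarray(image_points, dtype=float).reshape(-1, 2)
    if len(src) != len(dst):
        raise ValueError("point lists differ in length")
    if len(src) < 4:
        raise DegenerateGeometryError("at least four pairs required")
    if _collinear(src) or _collinear(dst):
        raise DegenerateGeometryError("points are collinear")

    if robust and len(src) > 4:
        rng = np.random.default_rng(seed)
        best, best_in = None, None
        for _ in range(n_iters):
            idx = rng.choice(len(src), 4, replace=False)
            try:
                H = _dlt(src[idx], dst[idx])
            except DegenerateGeometryError:
                continue
            err = np.linalg.norm(apply_homography(H, src) - dst, axis=1)
            inl = err < inlier_px
            if best_in is None or inl.sum() > best_in.sum():
                best, best_in = H, inl
        if best is None or best_in.sum() < 4:
            raise DegenerateGeometryError("no non-degenerate sample found")
        H = _dlt(src[best_in], dst[best_in])
    else:
        H = _dlt(src, dst)
    res = np.linalg.norm(apply_homography(H, src) - dst, axis=1)
    return H, res


def apply_homography(H: np.ndarray, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ np.asarray(H).T
    w = hom[:, 2]
    out = np.full((len(pts), 2), np.nan)
    ok = np.abs(w) > 1e-9
    out[ok] = hom[ok, :2] / w[ok, None]
    return out


def predict_missing(H: np.ndarray, ref_points_missing) -> tuple[np.ndarray, np.ndarray]:
    """Project reference points through ``H``; returns ``(points, valid)``
    where points mapping towards the line at infinity are flagged invalid."""
    pts = apply_homography(H, ref_points_missing)
    return pts, np.isfinite(pts).all(axis=1)


# -- sparse pyramidal Lucas-Kanade flow -------------------------------------

@dataclass(frozen=True)
class FlowConfig:
    window: int = 21            # odd patch side, px
    levels: int = 3             # pyramid levels
    iterations: int = 12        # Gauss-Newton iterations per level
    fb_threshold: float = 1.0   # forward-backward consistency gate, px
    min_eigen: float = 1e-3     # gradient-matrix conditioning floor


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    from scipy.ndimage import gaussian_filter

    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        sm = gaussian_filter(pyr[-1], 1.0)
        pyr.append(sm[::2, ::2])
    return pyr


def _patch(img: np.ndarray, centre: np.ndarray, half: int) -> np.ndarray:
    gy, gx = np.mgrid[-half:half + 1, -half:half + 1]
    coords = np.stack([gy + centre[1], gx + centre[0]])
    return map_coordinates(img, coords.reshape(2, -1), order=1,
                           mode="nearest").reshape(gy.shape)


def _lk_single(prev: list[np.ndarray], cur: list[np.ndarray],
               p0: np.ndarray, cfg: FlowConfig) -> tuple[np.ndarray, bool]:
    half = cfg.window // 2
    scale = 2.0 ** (len(prev) - 1)
    g = np.zeros(2)
    for lvl in range(len(prev) - 1, -1, -1):
        I, J = prev[lvl], cur[lvl]
        p = p0 / (2.0 ** lvl)
        T = _patch(I, p, half)
        Ty, Tx = np.gradient(T)
        G = np.array([[np.sum(Tx * Tx), np.sum(Tx * Ty)],
                      [np.sum(Tx * Ty), np.sum(Ty * Ty)]])
        eig = np.linalg.eigvalsh(G)
        if eig[0] < cfg.min_eigen * T.size:
            return p0 + g * 1.0, False
        Ginv = np.linalg.inv(G)
        for _ in range(cfg.iterations):
            Jp = _patch(J, p + g, half)
            e = Jp - T
            delta = -Ginv @ np.array([np.sum(Tx * e), np.sum(Ty * e)])
            g = g + delta
            if np.linalg.norm(delta) < 0.01:
                break
        if lvl > 0:
            g = g * 2.0
    return p0 + g, True


def track_points_flow(prev_image, cur_image, prev_points,
                      cfg: FlowConfig | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Track points between consecutive frames.

    Returns ``(points, status)``; a point succeeds only if the backward
    track returns to its start within ``fb_threshold`` px (and the local
    gradient matrix is well conditioned, which fails on textureless
    regions).
    """
    cfg = cfg or FlowConfig()
    prev_image = np.asarray(prev_image, dtype=float)
    cur_image = np.asarray(cur_image, dtype=float)
    if prev_image.shape != cur_image.shape:
        raise ValueError("frame size mismatch")
    pts = np.asarray(prev_points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point list")
    pts = np.atleast_2d(pts)
    pa = _pyramid(prev_image, cfg.levels)
    pb = _pyramid(cur_image, cfg.levels)
    out = np.zeros_like(pts)
    status = np.zeros(len(pts), dtype=bool)
    h, w = prev_image.shape
    for i, p in enumerate(pts):
        fwd, ok = _lk_single(pa, pb, p, cfg)
        if not ok or not (0 <= fwd[0] < w and 0 <= fwd[1] < h):
            out[i] = fwd
            continue
        back, ok2 = _lk_single(pb, pa, fwd, cfg)
        out[i] = fwd
        status[i] = ok2 and np.linalg.norm(back - p) <= cfg.fb_threshold
    return out, status


# -- per-sequence state machine ---------------------------------------------

class TrackMode(enum.Enum):
    DETECTED = "detected"
    FLOW_TRACKING = "flow_tracking"
    LOST = "lost"


@dataclass
class TrackState:
    """Tracking memory between frames of one sequence."""

    mode: TrackMode = TrackMode.LOST
    ref_ids: np.ndarray | None = None       # model dot ids of the pattern
    ref_points: np.ndarray | None = None    # flat reference coords, mm
    image_points: np.ndarray | None = None  # last known projections, px
    homography: np.ndarray | None = None
    prev_frame: np.ndarray | None = None
    frames_since_detection: int = 0
    pattern: str | None = None


@dataclass
class StepResult:
    mode: TrackMode
    ids: np.ndarray | None = None
    image_points: np.ndarray | None = None  # tracked + recovered positions
    tracked_mask: np.ndarray | None = None  # True where measured (not filled)
    homography: np.ndarray | None = None


def step(state: TrackState, frame: np.ndarray, detection,
         flow_cfg: FlowConfig | None = None, seed: int = 0) -> StepResult:
    """Advance the tracker by one frame.

    ``detection`` is ``None`` on detection failure, else a tuple
    ``(pattern, ids, ref_points_mm, image_points_px)`` from the
    identification stage (detection is attempted on every frame
    regardless of the current mode).
    """
    gray = np.asarray(frame, dtype=float)
    if detection is not None:
        pattern, ids, ref, img = detection
        H, _ = estimate_homography(ref, img, robust=len(ref) > 4, seed=seed)
        state.mode = TrackMode.DETECTED
        state.pattern = pattern
        state.ref_ids = np.asarray(ids)
        state.ref_points = np.asarray(ref, dtype=float)
        state.image_points = np.asarray(img, dtype=float)
        state.homography = H
        state.frames_since_detection = 0
        state.prev_frame = gray
        return StepResult(state.mode, state.ref_ids, state.image_points,
                          np.ones(len(ids), dtype=bool), H)

    if state.mode is TrackMode.LOST or state.prev_frame is None:
        state.prev_frame = gray
        return StepResult(TrackMode.LOST)

    new_pts, ok = track_points_flow(state.prev_frame, gray,
                                    state.image_points, flow_cfg)
    if ok.sum() >= 4 and not _collinear(state.ref_points[ok]):
        try:
            H, res = estimate_homography(state.ref_points[ok], new_pts[ok],
                                         robust=ok.sum() > 4, seed=seed)
        except DegenerateGeometryError:
            H = None
        if H is not None:
            inl = np.zeros_like(ok)
            inl[ok] = res < 3.0
            if inl.sum() >= 4:
                filled = new_pts.copy()
                missing, valid = predict_missing(H, state.ref_points[~inl])
                filled[~inl] = missing
                state.mode = TrackMode.FLOW_TRACKING
                state.image_points = filled
                state.homography = H
                state.frames_since_detection += 1
                state.prev_frame = gray
                return StepResult(state.mode, state.ref_ids, filled, inl, H)
    state.mode = TrackMode.LOST
    state.prev_frame = gray
    state.frames_since_detection += 1
    return StepResult(TrackMode.LOST)
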
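"""Debug overlays: marker outline, detections and pose axes on frames.

Colour conventions follow the tracker's status reporting: a green marker
outline for frames localised by detection, yellow when the temporal
(flow) fallback produced the localisation, and the pose drawn as RGB
axes (x red, y green, z blue) anchored at the marker origin.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, line

from .camera import CameraIntrinsics, project_points
from .geometry import MarkerSpec, pattern_template
from .tracking import TrackMode, apply_homography

GREEN = (60, 220, 60)
YELLOW = (235, 220, 40)
RED = (230, 50, 50)
BLUE = (60, 90, 230)


def _to_rgb(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray)
    if g.ndim == 3:
        return g.copy()
    return np.repeat(g[..., None], 3, axis=2).astype(np.uint8)


def _draw_line(img, p0, p1, color):
    h, w = img.shape[:2]
    p0 = np.clip(p0, [0, 0], [w - 1, h - 1])
    p1 = np.clip(p1, [0, 0], [w - 1, h - 1])
    rr, cc = line(int(p0[1]), int(p0[0]), int(p1[1]), int(p1[0]))
    img[rr, cc] = color


def draw_overlay(frame, result, spec: MarkerSpec, K: CameraIntrinsics) -> np.ndarray:
    """Annotate one frame with the tracker's :class:`FrameResult`."""
    img = _to_rgb(frame)
    colour = GREEN if result.mode is TrackMode.DETECTED else YELLOW
    fd = result.detection
    if fd is not None:
        for p in fd.patterns.values():
            tpl = pattern_template(spec, p.pattern)
            n = spec.dots_per_row
            corners = apply_homography(p.homography,
                                       tpl[[0, n - 1, 2 * n - 1, n]])
            for i in range(4):
                _draw_line(img, corners[i], corners[(i + 1) % 4], colour)
            for pt in p.image_points:
                rr, cc = disk((pt[1], pt[0]), 2.5, shape=img.shape[:2])
                img[rr, cc] = colour
    if result.pose is not None:
        origin3 = np.array([spec.pattern_length / 2.0, 0.0, 0.0])
        axes = 8.0 * np.eye(3) + origin3
        try:
            pts = project_points(K, result.pose, np.vstack([origin3, axes]))
            for axis_pt, col in zip(pts[1:], (RED, GREEN, BLUE)):
                _draw_line(img, pts[0], axis_pt, col)
        except ValueError:
            pass
    return img
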
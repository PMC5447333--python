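"""Chessboard-vertex detection via a ring-sampled corner response.

For every pixel, 16 intensities are sampled on a circle of fixed radius
at equal angular spacing.  A chessboard corner shows four alternating
90-degree quadrants, so diametrically opposite samples agree while
adjacent quadrants differ; the response is

    response = sum_response - difference_response - mean_response

where the *sum response* is the largest contrast between complementary
half-sets of the eight opposite-pair sums (maximal for the quadrant
layout), the *difference response* penalises opposite-pair disagreement
(edges), and the *mean response* penalises pixels whose local intensity
mean deviates from a larger spatial mean (blob interiors).  Peaks of the
response map above a threshold survive non-maximum suppression and get an
orientation label: the dark-quadrant axis lives on a half-circle (a corner
is 180-degree symmetric), quantised into 8 labels of 22.5 degrees.  Label
0 means dark quadrants along the +x image axis; labels increase toward
+y (image down).  A 90-degree checker-phase change shifts the label by 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, map_coordinates

from .geometry import LABEL_STEP_DEG, N_ORIENTATION_LABELS

__all__ = [
    "VertexDetection",
    "VertexDetectorConfig",
    "RingOutOfBoundsError",
    "sample_ring",
    "corner_response",
    "orientation_from_samples",
    "response_map",
    "detect_vertices",
]

N_RING = 16
_ANGLES = 2.0 * math.pi * np.arange(N_RING) / N_RING


class RingOutOfBoundsError(ValueError):
    """The sampling ring does not fit inside the image."""


@dataclass
class VertexDetection:
    position: np.ndarray        # (x, y), sub-pixel
    response: float
    orientation_label: int


@dataclass(frozen=True)
class VertexDetectorConfig:
    ring_radius: float = 5.0
    gaussian_sigma: float = 1.5      # pre-filter, px
    nms_window: int = 7
    rel_threshold: float = 0.15      # fraction of the global max response
    abs_threshold: float = 40.0      # grey-level floor for blank scenes
    local_mean_sigma: float = 2.0
    spatial_mean_sigma: float = 8.0
    mean_weight: float = 8.0


def sample_ring(image: np.ndarray, centre, radius: float) -> np.ndarray:
    """16 bilinear samples at angles ``2 pi k / 16`` starting on +x.

    Raises :class:`RingOutOfBoundsError` when the ring leaves the image;
    callers skip such pixels.
    """
    img = np.asarray(image, dtype=float)
    cx, cy = float(centre[0]), float(centre[1])
    h, w = img.shape
    if (cx - radius < 0 or cx + radius > w - 1
            or cy - radius < 0 or cy + radius > h - 1):
        raise RingOutOfBoundsError("sampling ring outside image bounds")
    xs = cx + radius * np.cos(_ANGLES)
    ys = cy + radius * np.sin(_ANGLES)
    return map_coordinates(img, np.stack([ys, xs]), order=1, mode="nearest")


def corner_response(samples: np.ndarray, local_mean: float,
                    spatial_mean: float, mean_weight: float = 8.0) -> float:
    """Scalar corner response for one 16-sample ring (larger = more
    corner-like; uniform patches score <= 0)."""
    s = np.asarray(samples, dtype=float)
    t = s[:8] + s[8:]
    total = t.sum()
    win = np.array([np.take(t, range(j, j + 4), mode="wrap").sum()
                    for j in range(8)])
    sum_resp = np.abs(2.0 * win - total).max()
    diff_resp = np.abs(s[:8] - s[8:]).sum()
    mean_resp = mean_weight * abs(local_mean - spatial_mean)
    return float(sum_resp - diff_resp - mean_resp)


def orientation_from_samples(samples: np.ndarray) -> int:
    """Orientation label from the second circular harmonic of the ring.

    The dark-axis angle ``phi`` (mod 180 deg) satisfies
    ``s(theta) ~ m - A cos(2 (theta - phi))``; the label is ``phi``
    quantised to 22.5-degree bins.
    """
    s = np.asarray(samples, dtype=float)
    c = np.sum(s * np.exp(-2j * _ANGLES))
    phi = -0.5 * np.angle(-c)         # radians, mod pi
    deg = math.degrees(phi) % 180.0
    return int(round(deg / LABEL_STEP_DEG)) % N_ORIENTATION_LABELS


def _ring_stack(img: np.ndarray, radius: float) -> np.ndarray:
    """(16, H, W) stack of ring samples for every pixel via shifted
    bilinear lookups (each sample offset is constant across the image)."""
    h, w = img.shape
    out = np.empty((N_RING, h, w))
    for k, ang in enumerate(_ANGLES):
        dx, dy = radius * math.cos(ang), radius * math.sin(ang)
        x0, y0 = math.floor(dx), math.floor(dy)
        fx, fy = dx - x0, dy - y0
        acc = np.zeros((h, w))
        for ox, wx in ((x0, 1 - fx), (x0 + 1, fx)):
            for oy, wy in ((y0, 1 - fy), (y0 + 1, fy)):
                if wx * wy == 0:
                    continue
                shifted = np.roll(np.roll(img, -oy, axis=0), -ox, axis=1)
                acc += wx * wy * shifted
        out[k] = acc
    return out


def response_map(image: np.ndarray,
                 params: VertexDetectorConfig | None = None) -> np.ndarray:
    """Corner response at every pixel (border band set to -inf)."""
    params = params or VertexDetectorConfig()
    img = gaussian_filter(np.asarray(image, dtype=float), params.gaussian_sigma)
    s = _ring_stack(img, params.ring_radius)
    t = s[:8] + s[8:]
    total = t.sum(axis=0)
    win = np.stack([sum(t[(j + i) % 8] for i in range(4)) for j in range(8)])
    sum_resp = np.abs(2.0 * win - total).max(axis=0)
    diff_resp = np.abs(s[:8] - s[8:]).sum(axis=0)
    local = gaussian_filter(img, params.local_mean_sigma)
    spatial = gaussian_filter(img, params.spatial_mean_sigma)
    resp = sum_resp - diff_resp - params.mean_weight * np.abs(local - spatial)
    b = int(math.ceil(params.ring_radius)) + 1
    resp[:b, :] = resp[-b:, :] = -np.inf
    resp[:, :b] = resp[:, -b:] = -np.inf
    return resp


def detect_vertices(image: np.ndarray,
                    params: VertexDetectorConfig | None = None,
                    ) -> list[VertexDetection]:
    """Gaussian pre-filter, response map, threshold, NMS, orientation."""
    params = params or VertexDetectorConfig()
    resp = response_map(image, params)
    peak = resp.max()
    if not np.isfinite(peak):
        return []
    thr = max(params.abs_threshold, params.rel_threshold * peak)
    nms = maximum_filter(resp, size=params.nms_window, mode="constant",
                         cval=-np.inf)
    ys, xs = np.nonzero((resp >= thr) & (resp == nms))
    smoothed = gaussian_filter(np.asarray(image, dtype=float),
                               params.gaussian_sigma)
    out: list[VertexDetection] = []
    h, w = resp.shape
    for y, x in zip(ys, xs):
        # sub-pixel refinement: response centroid over the 3x3 neighbourhood
        if 1 <= y < h - 1 and 1 <= x < w - 1:
            patch = resp[y - 1:y + 2, x - 1:x + 2]
            pw = np.clip(patch - patch.min(), 0, None)
            if pw.sum() > 0:
                gy, gx = np.mgrid[-1:2, -1:2]
                dy = float((pw * gy).sum() / pw.sum())
                dx = float((pw * gx).sum() / pw.sum())
            else:
                dy = dx = 0.0
        else:
            dy = dx = 0.0
        pos = np.array([x + dx, y + dy])
        try:
            samples = sample_ring(smoothed, pos, params.ring_radius)
        except RingOutOfBoundsError:
            continue
        out.append(VertexDetection(pos, float(resp[y, x]),
                                   orientation_from_samples(samples)))
    return out


def label_distance(a: int, b: int) -> int:
    """Circular distance between orientation labels (mod 8)."""
    d = abs(int(a) - int(b)) % N_ORIENTATION_LABELS
    return min(d, N_ORIENTATION_LABELS - d)
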
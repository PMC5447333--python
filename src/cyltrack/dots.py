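"""Circular-dot extraction by multi-threshold binarisation and blob filtering.

The printed dots are dark disks on a light tool surface.  A single global
threshold is fragile under illumination change, so the image is binarised
at a ladder of thresholds (default 70..100 step 10, object = intensity
below threshold); stable blobs reappear at several thresholds while
speckle and clutter do not.  Connected components are traced per binary
image and blobs are merged across thresholds when their centres agree
within a small radius.  A merged candidate survives four filters: pixel
area within a band, convexity (area over convex-hull area), circularity
``4 pi E / P**2`` and repeatability (the number of thresholds at which it
was re-detected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "Blob",
    "CandidateDot",
    "DotFilterCriteria",
    "binarize_multi",
    "trace_blobs",
    "circularity",
    "filter_and_merge",
    "detect_dots",
    "to_grayscale",
]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Standard luma conversion; pass-through for single-channel input."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(float)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError("expected a 2D grayscale or 3-channel colour raster")


@dataclass(frozen=True)
class DotFilterCriteria:
    """The detector's filter configuration (defaults as used throughout)."""

    thresholds: tuple[int, ...] = (70, 80, 90, 100)
    area_range: tuple[float, float] = (50.0, 2000.0)
    min_convexity: float = 0.85
    min_circularity: float = 0.75
    min_repeatability: int = 2
    merge_radius: float = 2.0     # px, cross-threshold centre association
    min_trace_area: float = 8.0   # speck suppression before filtering


@dataclass
class Blob:
    """One connected dark component of a single binary image."""

    centre: np.ndarray          # (x, y) sub-pixel centroid
    area: float                 # E, px^2
    perimeter: float            # P, px (diagonal steps weighted)
    convexity: float            # E / convex hull area
    threshold: int | None = None

    @property
    def circularity(self) -> float:
        return circularity(self.area, self.perimeter)


@dataclass
class CandidateDot:
    """A blob merged across thresholds, with the filter statistics."""

    centre: np.ndarray
    area: float
    perimeter: float
    convexity: float
    circularity: float
    repeat_count: int
    source_thresholds: list[int] = field(default_factory=list)


def binarize_multi(gray: np.ndarray, thresholds) -> list[np.ndarray]:
    """One boolean object mask per threshold (object = below threshold)."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if any(not 0 <= t <= 255 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 255]")
    gray = np.asarray(gray, dtype=float)
    return [gray < t for t in thresholds]


def trace_blobs(binary: np.ndarray, min_area: float = 0.0,
                threshold: int | None = None) -> list[Blob]:
    """Connected components (8-connectivity) with centroid, area,
    perimeter and convexity filled in."""
    lab = label(np.asarray(binary, dtype=bool), connectivity=2)
    out: list[Blob] = []
    for rp in regionprops(lab):
        if rp.area < max(min_area, 1):
            continue
        per = rp.perimeter
        if per <= 0:
            continue
        hull_area = rp.area_convex
        cy, cx = rp.centroid
        out.append(Blob(np.array([cx, cy]), float(rp.area), float(per),
                        float(rp.area / hull_area), threshold))
    return out


def circularity(E: float, P: float) -> float:
    """``4 pi E / P**2``: 1 for an ideal disk, pi/4 for a square."""
    if P <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * E / (P * P)


def filter_and_merge(blobs_per_threshold: list[list[Blob]],
                     criteria: DotFilterCriteria | None = None,
                     ) -> list[CandidateDot]:
    """Associate blobs across thresholds and apply the four filters.

    Blobs whose centres lie within ``merge_radius`` of a running candidate
    centre are merged; the candidate's centre is the mean of contributing
    centres and its shape statistics are medians over contributions.  A
    candidate is kept iff the area lies in ``area_range``, convexity and
    circularity meet their minima and it was seen at
    ``min_repeatability`` or more thresholds.
    """
    if not blobs_per_threshold:
        raise ValueError("need at least one threshold's blob list")
    criteria = criteria or DotFilterCriteria()
    groups: list[list[Blob]] = []
    centres: list[np.ndarray] = []
    for blobs in blobs_per_threshold:
        for b in blobs:
            if centres:
                d = np.linalg.norm(np.asarray(centres) - b.centre, axis=1)
                j = int(np.argmin(d))
                if d[j] <= criteria.merge_radius:
                    groups[j].append(b)
                    centres[j] = np.mean([g.centre for g in groups[j]], axis=0)
                    continue
            groups.append([b])
            centres.append(b.centre.copy())

    lo, hi = criteria.area_range
    out: list[CandidateDot] = []
    for grp, c in zip(groups, centres):
        area = float(np.median([g.area for g in grp]))
        per = float(np.median([g.perimeter for g in grp]))
        conv = float(np.median([g.convexity for g in grp]))
        circ = circularity(area, per)
        cand = CandidateDot(np.asarray(c), area, per, conv, circ,
                            repeat_count=len(grp),
                            source_thresholds=[g.threshold for g in grp])
        if (lo <= area <= hi and conv >= criteria.min_convexity
                and circ >= criteria.min_circularity
                and cand.repeat_count >= criteria.min_repeatability):
            out.append(cand)
    return out


def refine_centres(gray: np.ndarray, candidates: list[CandidateDot],
                   iterations: int = 2) -> list[CandidateDot]:
    """Sub-pixel centre refinement by darkness-weighted centroid.

    Binarising near the dark end of the edge transition expands the blob
    asymmetrically when the edge blur varies across the dot (strong
    foreshortening), biasing the binary centroid by a few tenths of a
    pixel.  Weighting every pixel by its normalised darkness integrates
    the whole transition symmetrically, which is unbiased to first order
    for any edge width.
    """
    img = np.asarray(gray, dtype=float)
    h, w = img.shape
    for cand in candidates:
        r = math.sqrt(cand.area / math.pi)
        half = int(math.ceil(1.6 * r + 4))
        c = cand.centre.copy()
        for _ in range(iterations):
            x0 = int(round(c[0])) - half
            y0 = int(round(c[1])) - half
            x1, y1 = x0 + 2 * half + 1, y0 + 2 * half + 1
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                break
            patch = img[y0:y1, x0:x1]
            hi = np.percentile(patch, 85)
            lo = np.percentile(patch, 15)
            if hi - lo < 10:
                break
            wgt = np.clip((hi - patch) / (hi - lo), 0.0, 1.0)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            mask = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 <= (r + 3.0) ** 2
            wgt = wgt * mask
            s = wgt.sum()
            if s <= 0:
                break
            c = np.array([(wgt * gx).sum() / s, (wgt * gy).sum() / s])
        cand.centre = c
    return candidates


def detect_dots(gray: np.ndarray,
                criteria: DotFilterCriteria | None = None) -> list[CandidateDot]:
    """Full dot-candidate pipeline on a grayscale raster."""
    criteria = criteria or DotFilterCriteria()
    masks = binarize_multi(gray, criteria.thresholds)
    per_thr = [trace_blobs(mask, criteria.min_trace_area, thr)
               for mask, thr in zip(masks, criteria.thresholds)]
    cands = filter_and_merge(per_thr, criteria)
    return refine_centres(gray, cands)
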
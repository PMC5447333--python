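"""Assigning model identities to detected dots and vertices.

The stages follow the marker's design.  Candidate dots are clustered by
single linkage at a scale-adaptive distance; each cluster is a candidate
two-row dot pattern.  The four sharp corners of the cluster's convex hull
are ordered using the fact that the two long edges (the rows) are nearly
parallel, a homography is fitted from the four corner correspondences,
and every detected dot inherits the identity of the nearest transformed
model dot.  The asymmetric shifted dot decides between the two
180-degree-related fits; whether the pattern is the *top* or the *bottom*
copy follows from the left/right order of the pattern's first and last
dot in the image (the tool cannot appear horizontally flipped, being
constrained by the incision point).  The symmetric middle pattern's
orientation is fixed the same way from the relative dot positions.
Finally, chessboard vertices are matched against positions predicted from
the pattern homography, and kept only when their measured orientation
label agrees with the label deduced from the pattern orientation; dots
lying on top of a detected vertex are discarded as checker-square false
positives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .camera import CameraIntrinsics
from .dots import CandidateDot, DotFilterCriteria, detect_dots
from .geometry import (MarkerSpec, ModelPointSet, PATTERNS, build_model_points,
                       pattern_template, template_corner_indices,
                       LABEL_STEP_DEG, N_ORIENTATION_LABELS, surface_normal)
from .tracking import (DegenerateGeometryError, apply_homography,
                       estimate_homography)
from .vertices import (VertexDetection, VertexDetectorConfig, detect_vertices,
                       label_distance)

__all__ = [
    "IdentifyConfig",
    "PatternDetection",
    "FrameDetection",
    "IdentificationError",
    "cluster_dots",
    "cluster_and_select",
    "order_endpoints",
    "assign_dot_identities",
    "classify_cluster",
    "assign_vertex_identities",
    "reject_dot_vertex_conflicts",
    "identify_frame",
]


class IdentificationError(RuntimeError):
    pass


@dataclass(frozen=True)
class IdentifyConfig:
    link_factor: float = 3.0          # x median nearest-neighbour distance
    sharp_angle_deg: float = 150.0    # hull corner sharpness threshold
                                      # (the asymmetric corner reaches ~145
                                      # degrees under strong foreshortening;
                                      # collinear row dots stay near 180)
    parallel_tol_deg: float = 25.0    # long-edge parallelism tolerance
    id_gate_factor: float = 0.4       # x transformed inter-dot spacing
    residual_gate_factor: float = 0.08
    min_assigned_dots: int = 8        # of the 2 x dots_per_row template
    min_cluster_coverage: float = 0.75  # matched fraction of the cluster
    align_tol_px: float = 2.0         # first/last dot left-right dead band
    vertex_gate_factor: float = 0.5   # x projected vertex pitch
    label_tolerance: int = 1
    fuse_patterns: bool = True        # classify every cluster, not only the largest
    conflict_radius_px: float = 4.0   # floor for dot/vertex conflict rejection
    area_ratio_tolerance: float = 1.4  # blob-area / grid-cell plausibility gate


@dataclass
class PatternDetection:
    """One classified dot pattern in one frame."""

    pattern: str
    dot_ids: np.ndarray          # model dot ids, aligned with image_points
    template_indices: np.ndarray
    image_points: np.ndarray     # (n, 2) px
    homography: np.ndarray       # pattern-local template mm -> image px
    residual: float              # mean assignment residual, px
    missing: list[int]           # unmatched template indices
    ambiguous_orientation: bool = False


@dataclass
class FrameDetection:
    """Everything the per-frame front end produced."""

    dots: list[CandidateDot]
    vertices: list[VertexDetection]
    patterns: dict[str, PatternDetection] = field(default_factory=dict)
    vertex_ids: np.ndarray | None = None      # model vertex ids
    vertex_points: np.ndarray | None = None   # matched detections, px
    status: str = "failed"                    # identified / partial / failed

    def best_pattern(self) -> PatternDetection | None:
        if not self.patterns:
            return None
        return min(self.patterns.values(),
                   key=lambda p: (-len(p.dot_ids), p.residual))

    def to_json(self) -> str:
        rec = {
            "status": self.status,
            "n_dots": len(self.dots),
            "n_vertices": len(self.vertices),
            "patterns": {
                name: {
                    "ids": p.dot_ids.tolist(),
                    "points": p.image_points.tolist(),
                    "residual": p.residual,
                    "homography": p.homography.tolist(),
                } for name, p in self.patterns.items()
            },
            "vertex_ids": None if self.vertex_ids is None
            else self.vertex_ids.tolist(),
        }
        return json.dumps(rec)


# -- clustering -------------------------------------------------------------

def cluster_dots(dots, link_distance: float | None = None,
                 config: IdentifyConfig | None = None,
                 image_centre=None) -> list[list[int]]:
    """Single-linkage clusters of candidate dots, largest first.

    ``link_distance`` defaults to ``link_factor`` times the median
    nearest-neighbour distance, making the clustering scale-invariant
    over the working range.  Ties in size are broken by the smaller mean
    distance to the image centre.
    """
    config = config or IdentifyConfig()
    pts = np.array([d.centre for d in dots], dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [[0]]
    tree = cKDTree(pts)
    if link_distance is None:
        nn, _ = tree.query(pts, k=2)
        link_distance = config.link_factor * float(np.median(nn[:, 1]))
    pairs = tree.query_pairs(link_distance)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = list(groups.values())
    centre = (np.zeros(2) if image_centre is None
              else np.asarray(image_centre, dtype=float))

    def tiebreak(c):
        return float(np.linalg.norm(pts[c] - centre, axis=1).mean())

    clusters.sort(key=lambda c: (-len(c), tiebreak(c)))
    return clusters


def cluster_and_select(dots, link_distance: float | None = None,
                       config: IdentifyConfig | None = None,
                       image_centre=None) -> list[int]:
    """The largest cluster (the marker, by the majority rule)."""
    clusters = cluster_dots(dots, link_distance, config, image_centre)
    if not clusters:
        raise IdentificationError("no candidate dots to cluster")
    return clusters[0]


# -- endpoint ordering ------------------------------------------------------

def order_endpoints(points: np.ndarray,
                    config: IdentifyConfig | None = None) -> np.ndarray:
    """Indices of the four sharp hull corners, cyclically ordered so that
    edges (1st -> 2nd) and (4th -> 3rd) are the two near-parallel long
    edges; the first corner is the topmost-then-leftmost of the two long
    edge starts.  Raises :class:`IdentificationError` on degenerate input.
    """
    config = config or IdentifyConfig()
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise IdentificationError("fewer than four dots")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise IdentificationError(f"degenerate hull: {exc}") from None
    hv = hull.vertices              # counter-clockwise cycle
    k = len(hv)
    angles = np.empty(k)
    for i in range(k):
        a, b, c = pts[hv[(i - 1) % k]], pts[hv[i]], pts[hv[(i + 1) % k]]
        u, v = a - b, c - b
        cosang = np.dot(u, v) / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-12)
        angles[i] = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    sharp = np.nonzero(angles < config.sharp_angle_deg)[0]
    if len(sharp) < 4:
        raise IdentificationError("fewer than four sharp hull corners")
    if len(sharp) > 4:
        sharp = sharp[np.argsort(angles[sharp])[:4]]
        sharp = np.sort(sharp)
    quad = hv[sharp]
    q = pts[quad]
    edges = [q[(i + 1) % 4] - q[i] for i in range(4)]
    lens = [np.linalg.norm(e) for e in edges]

    def par_angle(e1, e2):
        c = abs(np.dot(e1, e2)) / max(np.linalg.norm(e1) * np.linalg.norm(e2), 1e-12)
        return math.degrees(math.acos(np.clip(c, 0.0, 1.0)))

    if lens[0] + lens[2] >= lens[1] + lens[3]:
        long_pair, start = (0, 2), 0
    else:
        long_pair, start = (1, 3), 1
    if par_angle(edges[long_pair[0]], edges[long_pair[1]]) > config.parallel_tol_deg:
        raise IdentificationError("long edges are not parallel")
    order = [(start + i) % 4 for i in range(4)]
    # two rotations keep the long edges in the (0->1), (3->2) slots;
    # pick the one whose first corner is topmost-then-leftmost
    cand_a = [quad[order[i]] for i in range(4)]
    cand_b = [quad[order[(i + 2) % 4]] for i in range(4)]

    def keyof(c):
        p = pts[c[0]]
        return (p[1], p[0])

    return np.array(min((cand_a, cand_b), key=keyof))


# -- identity assignment ----------------------------------------------------

def _greedy_match(detected: np.ndarray, projected: np.ndarray,
                  gate: float) -> list[tuple[int, int, float]]:
    """One-to-one nearest matching (detected idx, template idx, dist)."""
    D = np.linalg.norm(detected[:, None, :] - projected[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
    used_i, used_j, out = set(), set(), []
    for i, j in order:
        if D[i, j] > gate:
            break
        if i in used_i or j in used_j:
            continue
        used_i.add(i); used_j.add(j)
        out.append((int(i), int(j), float(D[i, j])))
    return out


def assign_dot_identities(points: np.ndarray, endpoints: np.ndarray,
                          template: np.ndarray,
                          config: IdentifyConfig | None = None):
    """Fit the template through the sorted endpoints and label every dot.

    Both 180-degree-related endpoint correspondences are tried (mirrored
    ones are excluded by the no-horizontal-flip assumption); the fit that
    explains more dots with smaller residual wins.  Returns
    ``(matches, H, residual, orientation)`` with matches as
    ``(detected_idx, template_idx, dist)`` triplets.
    """
    config = config or IdentifyConfig()
    pts = np.asarray(points, dtype=float)
    n = len(template) // 2
    tc = (0, n - 1, 2 * n - 1, n)
    corners_img = pts[endpoints]
    best = None
    for orient in (0, 1):
        idx = [tc[(i + 2 * orient) % 4] for i in range(4)]
        try:
            H, _ = estimate_homography(template[idx], corners_img)
        except DegenerateGeometryError:
            continue
        proj = apply_homography(H, template)
        if not np.all(np.isfinite(proj)):
            continue
        spacing = float(np.median(
            np.linalg.norm(np.diff(proj[:n], axis=0), axis=1)))
        matches = _greedy_match(pts, proj, config.id_gate_factor * spacing)
        if len(matches) < 4:
            continue
        resid = float(np.mean([m[2] for m in matches]))
        score = (-len(matches), resid)
        if best is None or score < best[0]:
            best = (score, matches, H, resid, orient, spacing)
    if best is None:
        raise IdentificationError("no endpoint correspondence fits the template")
    _, matches, H, resid, orient, spacing = best
    if resid > config.residual_gate_factor * spacing:
        raise IdentificationError("template fit residual too large")
    if len(matches) < config.min_cluster_coverage * len(pts):
        raise IdentificationError("template explains too little of the cluster")
    # refine the homography on all matched pairs
    if len(matches) > 4:
        di = np.array([m[0] for m in matches])
        ti = np.array([m[1] for m in matches])
        try:
            H, res = estimate_homography(template[ti], pts[di])
            resid = float(res.mean())
        except DegenerateGeometryError:
            pass
    return matches, H, resid, orient


def classify_cluster(points: np.ndarray, spec: MarkerSpec,
                     config: IdentifyConfig | None = None) -> PatternDetection:
    """Full classification of one cluster: endpoints, identities, label.

    Tries the asymmetric (top) and the symmetric (middle) templates; the
    winning fit's orientation in the image decides the final label via
    the first-dot-left-of-last rule.
    """
    config = config or IdentifyConfig()
    pts = np.asarray(points, dtype=float)
    endpoints = order_endpoints(pts, config)
    n = spec.dots_per_row
    best = None
    for tname in ("top", "middle"):
        template = pattern_template(spec, tname)
        try:
            matches, H, resid, orient = assign_dot_identities(
                pts, endpoints, template, config)
        except IdentificationError:
            continue
        score = (-len(matches), resid)
        if best is None or score < best[0]:
            best = (score, tname, matches, H, resid, orient)
    if best is None:
        raise IdentificationError("cluster matches no pattern template")
    _, tname, matches, H, resid, orient = best
    if len(matches) < config.min_assigned_dots:
        raise IdentificationError("too few dots assigned to the template")

    template = pattern_template(spec, tname)
    proj = apply_homography(H, template)
    u_first, u_last = proj[0, 0], proj[n - 1, 0]
    ambiguous = abs(u_first - u_last) < config.align_tol_px
    if tname == "top":
        label = "top" if u_first < u_last else "bottom"
    else:
        # middle pattern: fix the 180-degree orientation the same way
        label = "middle"
        if u_first > u_last:
            # canonical reading direction: a 180-degree rotation of the
            # symmetric grid permutes template index k to 2n-1-k
            matches = [(di_, 2 * n - 1 - ti_, r) for di_, ti_, r in matches]

    per = 2 * n
    base = PATTERNS.index(label) * per
    di = np.array([m[0] for m in matches])
    ti = np.array([m[1] for m in matches])
    # final homography in the labelled pattern's own template frame
    ltemplate = pattern_template(spec, label)
    try:
        Hfin, res = estimate_homography(ltemplate[ti], pts[di])
        resid = float(res.mean())
    except DegenerateGeometryError as exc:
        raise IdentificationError(str(exc)) from None
    missing = sorted(set(range(per)) - set(ti.tolist()))
    return PatternDetection(
        pattern=label,
        dot_ids=base + ti,
        template_indices=ti,
        image_points=pts[di],
        homography=Hfin,
        residual=resid,
        missing=missing,
        ambiguous_orientation=bool(ambiguous),
    )


# -- vertex identities ------------------------------------------------------

#: vertex rows adjacent to each dot pattern (the wrap makes the bottom
#: vertex row border the top pattern across the seam)
_ADJACENT_VROWS = {
    "top": ("top", "bottom"),
    "middle": ("top", "middle"),
    "bottom": ("middle", "bottom"),
}


def _pattern_plane_frame(model: ModelPointSet, pattern: str):
    """Orthonormal in-plane basis of one pattern plus the affine map from
    plane coordinates to the pattern's flat template coordinates."""
    spec = model.spec
    ids = model.pattern_dot_ids(pattern)
    P = model.dot_xyz(ids)
    origin = P[0]
    e1 = np.array([1.0, 0.0, 0.0])
    n = spec.dots_per_row
    d = P[n] - P[0]
    e2 = d - np.dot(d, e1) * e1
    e2 /= np.linalg.norm(e2)
    normal = np.cross(e1, e2)

    def plane_coords(Q):
        Q = np.atleast_2d(Q) - origin
        off = Q @ normal
        Qp = Q - np.outer(off, normal)
        return np.stack([Qp @ e1, Qp @ e2], axis=-1)

    tpl = pattern_template(spec, pattern)
    pc = plane_coords(P)
    A_mat, res, *_ = np.linalg.lstsq(
        np.column_stack([pc, np.ones(len(pc))]), tpl, rcond=None)
    return plane_coords, A_mat, normal


def _homography_jacobian(H: np.ndarray, p) -> np.ndarray:
    x, y = float(p[0]), float(p[1])
    den = H[2, 0] * x + H[2, 1] * y + H[2, 2]
    u = (H[0, 0] * x + H[0, 1] * y + H[0, 2]) / den
    v = (H[1, 0] * x + H[1, 1] * y + H[1, 2]) / den
    J = np.array([[H[0, 0] - u * H[2, 0], H[0, 1] - u * H[2, 1]],
                  [H[1, 0] - v * H[2, 0], H[1, 1] - v * H[2, 1]]]) / den
    return J


def predict_vertices(model: ModelPointSet, det: PatternDetection):
    """Expected image positions and orientation labels of the vertex rows
    adjacent to a classified pattern.

    Positions come from the pattern homography applied to the vertex's
    orthogonal projection onto the pattern plane; labels from the pattern
    orientation via the homography Jacobian (which also absorbs the
    mirror-free 180-degree case).
    """
    spec = model.spec
    plane_coords, A_mat, _ = _pattern_plane_frame(model, det.pattern)
    out = []
    for row in _ADJACENT_VROWS[det.pattern]:
        for vid in model.row_vertex_ids(row):
            v = model.vertices[vid]
            pc = plane_coords(np.array(v.xyz))[0]
            tpl = np.array([pc[0], pc[1], 1.0]) @ A_mat
            img = apply_homography(det.homography, tpl)[0]
            if not np.all(np.isfinite(img)):
                continue
            # dark-axis direction: marker plane -> 3D tangent -> plane ->
            # template -> image
            phi = math.radians(v.base_label * LABEL_STEP_DEG)
            R = spec.cylinder_radius
            theta = v.xy[1] / R
            tangent = np.array([0.0, math.cos(theta), math.sin(theta)])
            d3 = math.cos(phi) * np.array([1.0, 0.0, 0.0]) + math.sin(phi) * tangent
            base = plane_coords(np.array(v.xyz))[0]
            tip = plane_coords(np.array(v.xyz) + 0.5 * d3)[0]
            dt = (np.append(tip, 1.0) @ A_mat) - (np.append(base, 1.0) @ A_mat)
            J = _homography_jacobian(det.homography, tpl)
            w = J @ dt
            ang = math.degrees(math.atan2(w[1], w[0])) % 180.0
            label = int(round(ang / LABEL_STEP_DEG)) % N_ORIENTATION_LABELS
            out.append((vid, img, label))
    return out


def assign_vertex_identities(vertices: list[VertexDetection],
                             pattern_dets, model: ModelPointSet,
                             config: IdentifyConfig | None = None):
    """Match detected vertices to model ids via the classified patterns.

    A detection is accepted only within the gating radius of a predicted
    position *and* with an orientation label within ``label_tolerance``
    of the deduced one.  Returns ``(vertex_ids, points, det_indices)``.
    """
    config = config or IdentifyConfig()
    if not pattern_dets or not vertices:
        return np.array([], dtype=int), np.zeros((0, 2)), np.array([], dtype=int)
    preds: dict[int, tuple[np.ndarray, int]] = {}
    for det in pattern_dets:
        for vid, img, label in predict_vertices(model, det):
            if vid not in preds:
                preds[vid] = (img, label)
    if not preds:
        return np.array([], dtype=int), np.zeros((0, 2)), np.array([], dtype=int)
    vids = list(preds)
    ppos = np.array([preds[v][0] for v in vids])
    plab = [preds[v][1] for v in vids]
    pitch = model.spec.vertex_pitch()
    # projected pitch from neighbouring predictions of the same row
    if len(ppos) >= 2:
        d = np.linalg.norm(np.diff(ppos, axis=0), axis=1)
        gate = config.vertex_gate_factor * float(np.median(d))
    else:
        gate = config.vertex_gate_factor * pitch * 10.0
    dpos = np.array([v.position for v in vertices])
    D = np.linalg.norm(dpos[:, None, :] - ppos[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
    used_d, used_p = set(), set()
    out_ids, out_pts, out_idx = [], [], []
    for i, j in order:
        if D[i, j] > gate:
            break
        if i in used_d or j in used_p:
            continue
        if label_distance(vertices[i].orientation_label,
                          plab[j]) > config.label_tolerance:
            continue
        used_d.add(i); used_p.add(j)
        out_ids.append(vids[j])
        out_pts.append(vertices[i].position)
        out_idx.append(int(i))
    return (np.array(out_ids, dtype=int),
            np.array(out_pts, dtype=float).reshape(-1, 2),
            np.array(out_idx, dtype=int))


def reject_dot_vertex_conflicts(dots, vertices,
                                radius: float | None = None,
                                config: IdentifyConfig | None = None):
    """Drop candidate dots sitting on a detected chessboard vertex.

    The dark triangle/square shapes around a vertex can pass the blob
    filters (a blurred square's circularity exceeds 0.75), so any dot
    centred within ``radius`` px of a detected vertex is discarded.
    """
    config = config or IdentifyConfig()
    if not vertices or not dots:
        return list(dots)
    if radius is None:
        radius = config.conflict_radius_px
    vpos = np.array([v.position for v in vertices])
    keep = []
    for d in dots:
        if np.min(np.linalg.norm(vpos - d.centre, axis=1)) > radius:
            keep.append(d)
    return keep


def plausible_dot_areas(det: PatternDetection, dot_objs, spec: MarkerSpec,
                        config: IdentifyConfig | None = None) -> bool:
    """Check that the classified blobs are dot-sized for the fitted grid.

    The ratio of blob area to the projected grid cell (x pitch times row
    gap) is invariant to perspective foreshortening and distinguishes
    printed dots from the dark checker squares of a vertex row, whose
    fill ratio is about 1.7x larger.
    """
    config = config or IdentifyConfig()
    expected = math.pi * spec.dot_radius ** 2 / (spec.dot_spacing * spec.dot_row_gap)
    template = pattern_template(spec, det.pattern)
    n = spec.dots_per_row
    p0, p1, pr = apply_homography(
        det.homography, template[[0, 1, n]])
    pitch = float(np.linalg.norm(p1 - p0))
    gap = float(np.linalg.norm(pr - p0))
    if pitch * gap <= 0:
        return False
    centres = np.array([d.centre for d in dot_objs])
    areas = []
    for p in det.image_points:
        j = int(np.argmin(np.linalg.norm(centres - p, axis=1)))
        areas.append(dot_objs[j].area)
    ratio = float(np.median(areas)) / (pitch * gap)
    return ratio <= config.area_ratio_tolerance * expected


def _gap_vertex_label(det: PatternDetection, spec: MarkerSpec) -> int:
    """Orientation label of the spurious corner response that appears
    midway between the two rows of a genuine dot pattern (its dark axis
    is the row-to-row direction)."""
    template = pattern_template(spec, det.pattern)
    centre = template.mean(axis=0)
    J = _homography_jacobian(det.homography, centre)
    w = J @ np.array([0.0, 1.0])
    ang = math.degrees(math.atan2(w[1], w[0])) % 180.0
    return int(round(ang / LABEL_STEP_DEG)) % N_ORIENTATION_LABELS


def is_checker_row_cluster(det: PatternDetection,
                           vertices: list[VertexDetection],
                           spec: MarkerSpec,
                           config: IdentifyConfig | None = None) -> bool:
    """Veto a classified cluster that is really a row of checker crosses.

    The dark squares of a vertex row form a two-row grid that fits the
    dot-pattern template projectively.  The giveaway is the orientation
    of the corner features on the grid's midline: between the rows of a
    genuine dot pattern any corner response has its dark axis along the
    row-to-row direction, whereas the midline of a checker row carries
    the true vertices whose dark axis is diagonal (two labels away).
    """
    config = config or IdentifyConfig()
    if not vertices:
        return False
    template = pattern_template(spec, det.pattern)
    n = spec.dots_per_row
    mids = 0.5 * (template[:n] + template[n:2 * n])
    proj = apply_homography(det.homography, mids)
    row_gap = float(np.linalg.norm(
        apply_homography(det.homography, template[:1])
        - apply_homography(det.homography, template[n:n + 1])))
    gate = 0.5 * row_gap
    perp = _gap_vertex_label(det, spec)
    vpos = np.array([v.position for v in vertices])
    diag_votes = 0
    for p in proj:
        d = np.linalg.norm(vpos - p, axis=1)
        j = int(np.argmin(d))
        if d[j] > gate:
            continue
        if label_distance(vertices[j].orientation_label, perp) >= 2:
            diag_votes += 1
    return diag_votes >= 2


# -- frame-level driver -----------------------------------------------------

def identify_frame(gray: np.ndarray, spec: MarkerSpec,
                   model: ModelPointSet | None = None,
                   config: IdentifyConfig | None = None,
                   dot_criteria: DotFilterCriteria | None = None,
                   vertex_params: VertexDetectorConfig | None = None,
                   ) -> FrameDetection:
    """Detect, filter and identify everything in one grayscale frame."""
    config = config or IdentifyConfig()
    model = model or build_model_points(spec)
    dots = detect_dots(gray, dot_criteria)
    vertices = detect_vertices(gray, vertex_params)
    dots = reject_dot_vertex_conflicts(dots, vertices, config=config)
    fd = FrameDetection(dots=dots, vertices=vertices)
    if len(dots) < 4:
        return fd
    h, w = np.asarray(gray).shape[:2]
    pts = np.array([d.centre for d in dots])
    tree = cKDTree(pts) if len(pts) > 1 else None
    if tree is not None:
        nn, _ = tree.query(pts, k=2)
        base_link = config.link_factor * float(np.median(nn[:, 1]))
    else:
        base_link = None
    # classify clusters; a failing cluster is re-clustered at a tighter
    # link distance, which separates patterns merged across the
    # inter-pattern gap under strong foreshortening
    queue = [(cl, base_link, 0) for cl in
             cluster_dots(dots, base_link, config, (w / 2, h / 2))]
    while queue:
        cl, link, depth = queue.pop(0)
        if len(cl) < config.min_assigned_dots:
            continue
        det = None
        try:
            det = classify_cluster(pts[cl], spec, config)
        except IdentificationError:
            pass
        if det is not None and (
                not plausible_dot_areas(det, dots, spec, config)
                or is_checker_row_cluster(det, vertices, spec, config)):
            det = None   # a vertex row masquerading as a dot pattern
        if det is None:
            if depth < 8 and link is not None and len(cl) > config.min_assigned_dots:
                sub = cluster_dots([dots[i] for i in cl], 0.8 * link,
                                   config, (w / 2, h / 2))
                idx = np.asarray(cl)
                queue.extend((idx[s].tolist(), 0.8 * link, depth + 1)
                             for s in sub if len(s) >= config.min_assigned_dots)
            continue
        if det.pattern not in fd.patterns \
                or det.residual < fd.patterns[det.pattern].residual:
            fd.patterns[det.pattern] = det
        if not config.fuse_patterns:
            break
    if fd.patterns:
        fd.status = "identified"
        if any(p.ambiguous_orientation for p in fd.patterns.values()):
            fd.status = "partial"
        ids, vpts, _ = assign_vertex_identities(
            vertices, list(fd.patterns.values()), model, config)
        fd.vertex_ids, fd.vertex_points = ids, vpts
    return fd
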
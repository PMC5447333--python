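"""Hybrid-marker geometry on a cylindrical tool shaft.

The marker is a flat printed pattern wrapped once around a cylinder of
radius ``R``.  It combines three two-row circular-dot patterns (labelled
``top`` / ``middle`` / ``bottom``) used for pose estimation with three rows
of chessboard-style corner targets used to break the planar pose
ambiguity.  The top and bottom dot patterns are asymmetric (one dot of the
second row is shifted along the axis) and are 180-degree rotations of each
other, while the middle pattern is symmetric under a 180-degree in-plane
rotation; this is what lets the identification stage tell the patterns
apart from a single view.

Marker-plane coordinates are in millimetres with the origin at the
pattern's top-left corner, ``x`` along the cylinder axis and ``y`` along
the circumference.  The cylinder-local 3D frame keeps ``X`` along the
axis; the printed plane point ``(x, y)`` lands on the surface at::

    X = x,   Y = R sin(y / R),   Z = R (1 - cos(y / R))

so the seam ``y = 0`` lies in the ``Z = 0`` plane and every surface point
satisfies ``Y**2 + (Z - R)**2 == R**2``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

__all__ = [
    "MarkerSpec",
    "ModelPointSet",
    "DotPoint",
    "VertexPoint",
    "arc_geometry",
    "map_marker_to_cylinder",
    "unroll_cylinder_point",
    "build_model_points",
    "pattern_template",
    "render_marker_raster",
]

PATTERNS = ("top", "middle", "bottom")

#: orientation wheel: 8 labels of 22.5 degrees covering the [0, 180) range of
#: the dark-quadrant axis of a chessboard corner (the corner is symmetric
#: under 180-degree rotation, so orientation is only defined modulo 180).
N_ORIENTATION_LABELS = 8
LABEL_STEP_DEG = 180.0 / N_ORIENTATION_LABELS


@dataclass(frozen=True)
class MarkerSpec:
    """Complete geometric description of the hybrid pattern (mm units).

    Defaults describe the marker sized for a 10 mm diameter tool; use
    :meth:`for_tool_diameter` to scale the design for 6-14 mm shafts.
    """

    cylinder_radius: float = 5.0
    pattern_length: float = 17.0
    pattern_arc: float = 29.6
    dot_rows_per_pattern: int = 2
    dots_per_row: int = 5
    dot_diameter: float = 1.6
    dot_spacing: float = 3.2
    dot_row_gap: float = 2.4
    #: axial shift of the last dot of the second row in the asymmetric
    #: (top/bottom) patterns; the device that makes them orientable.
    asym_shift: float = 1.6
    vertex_rows: int = 3
    vertices_per_row: int = 5
    vertex_square_size: float = 1.2
    #: print level of the checker squares (0 = black, 255 = white).  The
    #: default mid-grey keeps the squares above the dot detector's
    #: binarisation thresholds (so they can never masquerade as dots)
    #: while leaving ample contrast for the ring corner response.
    vertex_ink_grey: int = 150
    #: first-dot-row y of the top/middle/bottom patterns; None = computed.
    pattern_row_y: tuple[float, float, float] | None = None
    #: centre y of the three vertex rows; None = computed.
    vertex_row_y: tuple[float, float, float] | None = None
    x_margin: float = 1.2

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        for name in ("pattern_length", "pattern_arc", "dot_diameter",
                     "dot_spacing", "dot_row_gap", "vertex_square_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pattern_arc > 2 * math.pi * self.cylinder_radius + 1e-9:
            raise ValueError("pattern_arc exceeds the cylinder circumference "
                             "(the marker may wrap at most once)")
        if self.dot_rows_per_pattern != 2:
            raise ValueError("each dot pattern has exactly two rows")
        if self.dots_per_row < 3:
            raise ValueError("need at least 3 dots per row")

    # -- derived layout ---------------------------------------------------

    @property
    def dot_radius(self) -> float:
        return 0.5 * self.dot_diameter

    def pattern_rows(self) -> tuple[float, float, float]:
        """y coordinate of the first dot row of each pattern."""
        if self.pattern_row_y is not None:
            return tuple(self.pattern_row_y)
        # packed layout: pattern block, gap holding a vertex row, repeat.
        g, gap = self.dot_row_gap, self._inter_pattern_gap()
        y0 = self.x_margin  # same margin circumferentially
        return (y0, y0 + g + gap, y0 + 2 * (g + gap))

    def vertex_row_centres(self) -> tuple[float, float, float]:
        if self.vertex_row_y is not None:
            return tuple(self.vertex_row_y)
        rows = self.pattern_rows()
        g, gap = self.dot_row_gap, self._inter_pattern_gap()
        mid01 = rows[0] + g + 0.5 * gap
        mid12 = rows[1] + g + 0.5 * gap
        below = rows[2] + g + 0.5 * gap
        return (mid01, mid12, below)

    def _inter_pattern_gap(self) -> float:
        # distance from a pattern's second dot row to the next pattern's
        # first row; must exceed the clustering link distance (3x the
        # within-pattern nearest-neighbour spacing) so patterns separate.
        return 10.0 / 3.0 * min(self.dot_row_gap, self.dot_spacing)

    def vertex_pitch(self) -> float:
        return self.dot_spacing

    @classmethod
    def for_tool_diameter(cls, diameter_mm: float) -> "MarkerSpec":
        """Scale the default 10 mm design to another shaft diameter."""
        s = diameter_mm / 10.0
        base = cls()
        return replace(
            base,
            cylinder_radius=base.cylinder_radius * s,
            pattern_length=base.pattern_length * s,
            pattern_arc=base.pattern_arc * s,
            dot_diameter=base.dot_diameter * s,
            dot_spacing=base.dot_spacing * s,
            dot_row_gap=base.dot_row_gap * s,
            asym_shift=base.asym_shift * s,
            vertex_square_size=base.vertex_square_size * s,
            x_margin=base.x_margin * s,
        )

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump({"marker": asdict(self)}, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source) -> "MarkerSpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                data = yaml.safe_load(io.StringIO(text))
            else:
                with open(text) as fh:
                    data = yaml.safe_load(fh)
        fields = data["marker"] if "marker" in data else data
        for key in ("pattern_row_y", "vertex_row_y"):
            if fields.get(key) is not None:
                fields[key] = tuple(fields[key])
        return cls(**fields)


# -- closed-form arc relations --------------------------------------------

def arc_geometry(alpha: float, R: float) -> tuple[float, float, float]:
    """Arc length, chord length and segment height for angle ``alpha``.

    Returns ``(A, C, h)`` with ``A = alpha * R``,
    ``C = 2 R sin(alpha / 2)`` and ``h = R (1 - cos(alpha / 2))``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not 0.0 <= alpha <= 2 * math.pi:
        raise ValueError("alpha must lie in [0, 2*pi]")
    A = alpha * R
    C = 2.0 * R * math.sin(alpha / 2.0)
    h = R * (1.0 - math.cos(alpha / 2.0))
    return A, C, h


def map_marker_to_cylinder(p, R: float) -> np.ndarray:
    """Map flat marker-plane points (mm) onto the cylinder surface.

    ``p`` is ``(..., 2)`` with ``y`` in ``[0, 2*pi*R]`` (one full wrap).
    Returns ``(..., 3)`` local coordinates ``(X, Y, Z)``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    x, y = p[..., 0], p[..., 1]
    if np.any(y < -1e-12) or np.any(y > 2 * math.pi * R + 1e-12):
        raise ValueError("y must lie in [0, 2*pi*R]")
    theta = y / R
    out = np.stack([x, R * np.sin(theta), R * (1.0 - np.cos(theta))], axis=-1)
    return out[0] if scalar else out


def unroll_cylinder_point(P, R: float) -> np.ndarray:
    """Inverse of :func:`map_marker_to_cylinder` (surface points only)."""
    P = np.asarray(P, dtype=float)
    scalar = P.ndim == 1
    P = np.atleast_2d(P)
    theta = np.arctan2(P[..., 1], R - P[..., 2])
    theta = np.mod(theta, 2 * math.pi)
    out = np.stack([P[..., 0], R * theta], axis=-1)
    return out[0] if scalar else out


def surface_normal(P, R: float) -> np.ndarray:
    """Outward unit normal of the cylinder surface at local points ``P``."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    n = np.stack([np.zeros(P.shape[0]), P[:, 1], P[:, 2] - R], axis=-1)
    return n / R


# -- model point sets ------------------------------------------------------

@dataclass(frozen=True)
class DotPoint:
    id: int
    pattern: str            # top / middle / bottom
    index: int              # 0..9 template index (row-major)
    xy: tuple[float, float]      # marker-plane mm
    xyz: tuple[float, float, float]  # cylinder-local mm


@dataclass(frozen=True)
class VertexPoint:
    id: int
    row: str                # top / middle / bottom
    base_label: int         # orientation label in the upright print
    xy: tuple[float, float]
    xyz: tuple[float, float, float]


def pattern_template(spec: MarkerSpec, pattern: str) -> np.ndarray:
    """2D dot layout of one pattern in pattern-local mm, row-major order.

    Index 0 is the pattern's *first* dot and index ``dots_per_row - 1`` the
    *last* dot (the pair used by the top-vs-bottom left/right rule).
    """
    n, s, g = spec.dots_per_row, spec.dot_spacing, spec.dot_row_gap
    row0 = np.stack([np.arange(n) * s, np.zeros(n)], axis=1)
    row1 = np.stack([np.arange(n) * s, np.full(n, g)], axis=1)
    if pattern in ("top", "bottom"):
        row1[-1, 0] += spec.asym_shift     # the asymmetry device
    pts = np.vstack([row0, row1])
    if pattern == "bottom":
        # bottom pattern is the top pattern rotated 180 degrees in-plane
        centre = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
        pts = 2.0 * centre - pts
    elif pattern not in ("top", "middle"):
        raise ValueError(f"unknown pattern {pattern!r}")
    return pts


def template_corner_indices(spec: MarkerSpec) -> tuple[int, int, int, int]:
    """Template indices of the four pattern corners in cyclic order
    (row0-first, row0-last, row1-last, row1-first)."""
    n = spec.dots_per_row
    return (0, n - 1, 2 * n - 1, n)


@dataclass
class ModelPointSet:
    """All marker features with identities, flat and 3D coordinates."""

    spec: MarkerSpec
    dots: list[DotPoint]
    vertices: list[VertexPoint]

    # -- array accessors ---------------------------------------------------

    def dot_xyz(self, ids=None) -> np.ndarray:
        sel = self.dots if ids is None else [self.dots[i] for i in ids]
        return np.array([d.xyz for d in sel], dtype=float)

    def dot_xy(self, ids=None) -> np.ndarray:
        sel = self.dots if ids is None else [self.dots[i] for i in ids]
        return np.array([d.xy for d in sel], dtype=float)

    def vertex_xyz(self, ids=None) -> np.ndarray:
        sel = self.vertices if ids is None else [self.vertices[i] for i in ids]
        return np.array([v.xyz for v in sel], dtype=float)

    def vertex_xy(self, ids=None) -> np.ndarray:
        sel = self.vertices if ids is None else [self.vertices[i] for i in ids]
        return np.array([v.xy for v in sel], dtype=float)

    def pattern_dot_ids(self, pattern: str) -> list[int]:
        return [d.id for d in self.dots if d.pattern == pattern]

    def row_vertex_ids(self, row: str) -> list[int]:
        return [v.id for v in self.vertices if v.row == row]

    def dot_boundary_xyz(self, ids=None, n_samples: int = 24) -> np.ndarray:
        """3D boundary rings of the (curved) printed dots, ``(n, k, 3)``.

        The projection of a dot's centre is not quite the centroid of the
        dot's projected image once the disk wraps around the cylinder;
        pose refinement therefore predicts the measured centroid from
        these boundary rings instead of the centre points.
        """
        sel = self.dots if ids is None else [self.dots[i] for i in ids]
        r = self.spec.dot_radius
        ang = 2 * np.pi * np.arange(n_samples) / n_samples
        ring = r * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        out = np.empty((len(sel), n_samples, 3))
        for i, d in enumerate(sel):
            out[i] = map_marker_to_cylinder(np.asarray(d.xy) + ring,
                                            self.spec.cylinder_radius)
        return out

    def verify_on_surface(self, tol: float = 1e-9) -> float:
        """Max deviation of Y**2 + (Z-R)**2 from R**2 over all points."""
        R = self.spec.cylinder_radius
        pts = np.vstack([self.dot_xyz(), self.vertex_xyz()])
        dev = np.abs(pts[:, 1] ** 2 + (pts[:, 2] - R) ** 2 - R ** 2)
        worst = float(dev.max())
        if worst > tol:
            raise AssertionError(f"model point off the cylinder surface by {worst}")
        return worst

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [dict(kind="dot", id=d.id, label=d.pattern,
                     x=d.xy[0], y=d.xy[1],
                     X=d.xyz[0], Y=d.xyz[1], Z=d.xyz[2]) for d in self.dots]
        rows += [dict(kind="vertex", id=v.id, label=v.row,
                      x=v.xy[0], y=v.xy[1],
                      X=v.xyz[0], Y=v.xyz[1], Z=v.xyz[2]) for v in self.vertices]
        pd.DataFrame(rows).to_csv(path, index=False)


def build_model_points(spec: MarkerSpec) -> ModelPointSet:
    """Instantiate every dot and vertex of the marker with identities.

    Dot ids are ``pattern_index * (2 * dots_per_row) + template_index``.
    Vertex ids run row-major over the three vertex rows.  The middle vertex
    row carries the 90-degree checker-phase shift, i.e. its base
    orientation label differs from the top/bottom rows by
    ``N_ORIENTATION_LABELS // 2`` labels.
    """
    R = spec.cylinder_radius
    per = 2 * spec.dots_per_row
    rows_y = spec.pattern_rows()
    dots: list[DotPoint] = []
    for pi, pattern in enumerate(PATTERNS):
        local = pattern_template(spec, pattern)
        origin = np.array([spec.x_margin, rows_y[pi]])
        xy = local + origin
        extent = xy[:, 1].max() + spec.dot_radius
        if xy[:, 0].max() + spec.dot_radius > spec.pattern_length + 1e-9 \
                or extent > spec.pattern_arc + 1e-9:
            raise ValueError("dot layout exceeds the pattern extent")
        xyz = map_marker_to_cylinder(xy, R)
        for k in range(per):
            dots.append(DotPoint(pi * per + k, pattern, k,
                                 tuple(xy[k]), tuple(xyz[k])))

    half = N_ORIENTATION_LABELS // 2
    base_a = N_ORIENTATION_LABELS // 4          # 45 deg dark axis
    vcentres = spec.vertex_row_centres()
    pitch = spec.vertex_pitch()
    span = (spec.vertices_per_row - 1) * pitch
    vx0 = 0.5 * (spec.pattern_length - span)
    vertices: list[VertexPoint] = []
    vid = 0
    for ri, row in enumerate(PATTERNS):
        label = base_a if ri != 1 else (base_a + half) % N_ORIENTATION_LABELS
        yc = vcentres[ri]
        if yc + spec.vertex_square_size > spec.pattern_arc + 1e-9:
            raise ValueError("vertex layout exceeds the pattern arc")
        for i in range(spec.vertices_per_row):
            xy = (vx0 + i * pitch, yc)
            xyz = tuple(map_marker_to_cylinder(np.array(xy), R))
            vertices.append(VertexPoint(vid, row, label, xy, xyz))
            vid += 1
    return ModelPointSet(spec, dots, vertices)


# -- print-ready raster -----------------------------------------------------

def render_marker_raster(spec: MarkerSpec, resolution: float = 10.0) -> np.ndarray:
    """Rasterise the flat marker at ``resolution`` px/mm (uint8, ink = 0).

    The raster doubles as the texture for the synthetic cylinder renderer;
    columns map to ``x`` (axis) and rows to ``y`` (circumference).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    W = math.ceil(spec.pattern_length * resolution)
    H = math.ceil(spec.pattern_arc * resolution)
    img = np.full((H, W), 255, dtype=np.uint8)
    # pixel-centre sample coordinates in mm
    xs = (np.arange(W) + 0.5) / resolution
    ys = (np.arange(H) + 0.5) / resolution

    mps = build_model_points(spec)
    r = spec.dot_radius
    for d in mps.dots:
        cx, cy = d.xy
        j0, j1 = np.searchsorted(xs, (cx - r - 0.2, cx + r + 0.2))
        i0, i1 = np.searchsorted(ys, (cy - r - 0.2, cy + r + 0.2))
        X, Y = np.meshgrid(xs[j0:j1], ys[i0:i1])
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
        img[i0:i1, j0:j1][mask] = 0

    s = spec.vertex_square_size
    for v in mps.vertices:
        cx, cy = v.xy
        # phase A (labels near 45 deg): dark squares in the (+x,+y) and
        # (-x,-y) quadrants; phase B (middle row): the other diagonal.
        phase_a = v.base_label == N_ORIENTATION_LABELS // 4
        quads = [(1, 1), (-1, -1)] if phase_a else [(1, -1), (-1, 1)]
        for qx, qy in quads:
            x_lo, x_hi = sorted((cx, cx + qx * s))
            y_lo, y_hi = sorted((cy, cy + qy * s))
            j0, j1 = np.searchsorted(xs, (x_lo, x_hi))
            i0, i1 = np.searchsorted(ys, (y_lo, y_hi))
            img[i0:i1, j0:j1] = spec.vertex_ink_grey
    return img
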
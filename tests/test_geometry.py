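"""Marker geometry: arc relations, cylinder mapping, model points, raster."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyltrack.geometry import (MarkerSpec, arc_geometry, build_model_points,
                               map_marker_to_cylinder, pattern_template,
                               render_marker_raster, unroll_cylinder_point)


class TestArcGeometry:
    @pytest.mark.parametrize("alpha,R,expected", [
        (0.0, 10.0, (0.0, 0.0, 0.0)),
        (math.pi, 1.0, (math.pi, 2.0, 1.0)),
        (math.pi / 2, 4.0, (6.2832, 5.6569, 1.1716)),
    ])
    def test_known_values(self, alpha, R, expected):
        A, C, h = arc_geometry(alpha, R)
        assert (A, C, h) == pytest.approx(expected, abs=1e-4)

    def test_numerical_oracle(self):
        # independent check: arc length by quadrature, chord and height
        # from endpoint coordinates on the circle
        alpha, R = 1.234, 3.7
        thetas = np.linspace(0, alpha, 20001)
        arc_num = np.trapezoid(np.full_like(thetas, R), thetas)
        p0 = np.array([R * math.sin(0), R * (1 - math.cos(0))])
        p1 = np.array([R * math.sin(alpha), R * (1 - math.cos(alpha))])
        chord_num = np.linalg.norm(p1 - p0)
        # height: max distance from the chord over the arc
        pts = np.stack([R * np.sin(thetas), R * (1 - np.cos(thetas))], axis=1)
        e = p1 - p0
        d = (e[0] * (pts[:, 1] - p0[1]) - e[1] * (pts[:, 0] - p0[0])) \
            / np.linalg.norm(e)
        A, C, h = arc_geometry(alpha, R)
        assert A == pytest.approx(arc_num, rel=1e-9)
        assert C == pytest.approx(chord_num, rel=1e-9)
        assert h == pytest.approx(np.abs(d).max(), abs=1e-6)

    def test_monotone_in_alpha(self):
        alphas = np.linspace(0, math.pi, 50)
        vals = np.array([arc_geometry(a, 2.5) for a in alphas])
        assert np.all(np.diff(vals, axis=0) >= -1e-12)

    @pytest.mark.parametrize("alpha,R", [(-0.1, 1.0), (7.0, 1.0), (1.0, 0.0),
                                         (1.0, -2.0)])
    def test_invalid_parameters(self, alpha, R):
        with pytest.raises(ValueError):
            arc_geometry(alpha, R)


class TestCylinderMapping:
    @pytest.mark.parametrize("p,R,expected", [
        ((5.0, 0.0), 3.0, (5.0, 0.0, 0.0)),
        ((0.0, math.pi), 2.0, (0.0, 2.0, 2.0)),          # quarter turn
        ((1.0, 3 * math.pi), 3.0, (1.0, 0.0, 6.0)),      # half turn, Z = 2R
        ((0.0, 1.0), 1.0, (0.0, 0.84147, 0.45970)),
    ])
    def test_known_points(self, p, R, expected):
        assert map_marker_to_cylinder(np.array(p), R) == pytest.approx(
            expected, abs=1e-5)

    @given(x=st.floats(-50, 50), y=st.floats(0, 1.0), R=st.floats(0.5, 50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_surface_invariant(self, x, y, R):
        X, Y, Z = map_marker_to_cylinder(np.array([x, y * 2 * math.pi * R]), R)
        assert Y ** 2 + (Z - R) ** 2 == pytest.approx(R ** 2, abs=1e-9 * R * R)
        assert X == x

    def test_round_trip(self, rng):
        R = 4.2
        pts = np.stack([rng.uniform(0, 10, 200),
                        rng.uniform(0, 2 * math.pi * R * 0.999, 200)], axis=1)
        back = unroll_cylinder_point(map_marker_to_cylinder(pts, R), R)
        assert np.allclose(back, pts, atol=1e-6)

    def test_planar_limit(self):
        # as R grows with y fixed the cylinder flattens out
        # (Z ~ y**2 / 2R, below 1e-6 mm at R = 1e6)
        out = map_marker_to_cylinder(np.array([3.0, 1.0]), 1e6)
        assert out == pytest.approx([3.0, 1.0, 0.0], abs=1e-6)

    @pytest.mark.parametrize("y", [-0.5, 100.0])
    def test_domain_errors(self, y):
        with pytest.raises(ValueError):
            map_marker_to_cylinder(np.array([0.0, y]), 2.0)

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            map_marker_to_cylinder(np.array([0.0, 0.0]), -1.0)


class TestModelPoints:
    def test_counts_and_ids(self, model):
        assert len(model.dots) == 30
        assert [d.id for d in model.dots] == list(range(30))
        assert len(model.vertices) == 15
        assert len({v.id for v in model.vertices}) == 15

    def test_all_points_on_surface(self, model):
        assert model.verify_on_surface(tol=1e-9) < 1e-9

    def test_bottom_is_rotated_top(self, spec):
        top = pattern_template(spec, "top")
        bottom = pattern_template(spec, "bottom")
        centre = 0.5 * (top.min(axis=0) + top.max(axis=0))
        assert np.allclose(bottom, 2 * centre - top)

    def test_middle_symmetric_under_rotation(self, spec):
        mid = pattern_template(spec, "middle")
        centre = 0.5 * (mid.min(axis=0) + mid.max(axis=0))
        rotated = 2 * centre - mid
        # the rotated point set equals the original as a set
        d = np.linalg.norm(rotated[:, None] - mid[None], axis=2)
        assert d.min(axis=1).max() < 1e-9

    def test_top_pattern_is_asymmetric(self, spec):
        top = pattern_template(spec, "top")
        centre = 0.5 * (top.min(axis=0) + top.max(axis=0))
        rotated = 2 * centre - top
        d = np.linalg.norm(rotated[:, None] - top[None], axis=2)
        assert d.min(axis=1).max() > 0.5 * spec.asym_shift

    def test_middle_vertex_row_phase_shift(self, model):
        from cyltrack.geometry import N_ORIENTATION_LABELS

        labels = {v.row: v.base_label for v in model.vertices}
        half = N_ORIENTATION_LABELS // 2
        assert (labels["middle"] - labels["top"]) % N_ORIENTATION_LABELS == half
        assert labels["top"] == labels["bottom"]

    def test_layout_overflow_raises(self):
        with pytest.raises(ValueError):
            build_model_points(MarkerSpec(pattern_length=8.0))

    def test_dot_boundaries_on_surface(self, model, spec):
        b = model.dot_boundary_xyz([0, 7, 23])
        R = spec.cylinder_radius
        assert b.shape == (3, 24, 3)
        dev = np.abs(b[..., 1] ** 2 + (b[..., 2] - R) ** 2 - R ** 2)
        assert dev.max() < 1e-9


class TestMarkerSpec:
    def test_yaml_round_trip(self, spec, tmp_path):
        path = tmp_path / "marker.yaml"
        spec.to_yaml(path)
        assert MarkerSpec.from_yaml(path) == spec

    @pytest.mark.parametrize("kwargs", [
        dict(cylinder_radius=-1.0),
        dict(pattern_arc=100.0),         # more than one wrap
        dict(dot_diameter=0.0),
        dict(dot_rows_per_pattern=3),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            MarkerSpec(**kwargs)

    @pytest.mark.parametrize("dia", [6.0, 8.0, 12.0, 14.0])
    def test_tool_diameter_scaling(self, dia):
        s = MarkerSpec.for_tool_diameter(dia)
        assert s.cylinder_radius == pytest.approx(dia / 2)
        assert s.pattern_arc <= 2 * math.pi * s.cylinder_radius + 1e-9
        build_model_points(s).verify_on_surface()


class TestRaster:
    def test_dimensions(self):
        s = MarkerSpec()
        img = render_marker_raster(s, 10.0)
        assert img.shape == (math.ceil(s.pattern_arc * 10),
                             math.ceil(s.pattern_length * 10))

    def test_deterministic(self, spec):
        a = render_marker_raster(spec, 10.0)
        b = render_marker_raster(spec, 10.0)
        assert np.array_equal(a, b)

    def test_ink_fraction_matches_analytic_area(self, spec):
        img = render_marker_raster(spec, 10.0)
        printed = np.mean(img < 255)
        n_dots = 30
        n_crosses = 15
        area = (n_dots * math.pi * spec.dot_radius ** 2
                + n_crosses * 2 * spec.vertex_square_size ** 2)
        expected = area / (spec.pattern_length * spec.pattern_arc)
        # pixel quantisation of 8 px disks costs about 2% at 10 px/mm
        assert printed == pytest.approx(expected, rel=0.03)

    def test_invalid_resolution(self, spec):
        with pytest.raises(ValueError):
            render_marker_raster(spec, 0.0)

    def test_grey_crosses_above_binarisation_ladder(self, spec):
        img = render_marker_raster(spec, 10.0)
        levels = np.unique(img)
        assert set(levels) == {0, spec.vertex_ink_grey, 255}
        assert spec.vertex_ink_grey > 100   # the top of the threshold ladder
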
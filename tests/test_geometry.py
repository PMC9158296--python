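"""Line/circle fitting, the bisector shaft axis, calibration and offset."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from femoffset import (
    DegenerateGeometryError,
    FemurModel3D,
    LandmarkPoint,
    LandmarkSet,
    Line2D,
    bisector,
    calibrate,
    fit_circle,
    fit_line,
    measure_offset,
    project,
)
from femoffset.geometry import geometric_sse, orthogonal_sse


def _line_oracle_sse(points, n_angles=20000):
    """Brute force: best orthogonal SSE over a fine grid of line angles.

    For a fixed direction the optimal line passes through the centroid, so the
    search is one-dimensional in the angle.
    """
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    normals = np.column_stack([-np.sin(angles), np.cos(angles)])
    sse = ((centered @ normals.T) ** 2).sum(axis=0)
    return float(sse.min())


def _circle_oracle(points, start):
    """Brute-force geometric circle fit via Nelder-Mead from a given start."""
    pts = np.asarray(points, float)

    def objective(params):
        c, r = params[:2], params[2]
        return float(np.sum((np.linalg.norm(pts - c, axis=1) - r) ** 2))

    res = minimize(objective, start, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return res.x, res.fun


class TestFitLine:
    @pytest.mark.parametrize(
        "points, direction",
        [
            ([(0, 0), (0, 1), (0, 2), (0, 3), (0, 4)], (0.0, 1.0)),
            ([(0, 0), (1, 1), (2, 2)], (np.sqrt(0.5), np.sqrt(0.5))),
            ([(0, 5), (1, 5), (2, 5), (7, 5)], (1.0, 0.0)),
        ],
    )
    def test_collinear_points_recover_exact_direction(self, points, direction):
        line = fit_line(points)
        assert line.direction == pytest.approx(direction, abs=1e-12)
        assert orthogonal_sse(points, line) < 1e-20

    def test_coincident_points_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line([(3.0, 4.0)] * 5)

    def test_near_vertical_noisy_points_match_grid_oracle(self, rng):
        """TLS fit beats a fine brute-force angle grid on near-vertical data,
        the regime where y-on-x regression would fail."""
        for _ in range(20):
            pts = np.column_stack([
                3.0 + rng.uniform(-0.1, 0.1, 5),
                np.linspace(0, 40, 5),
            ])
            line = fit_line(pts)
            assert orthogonal_sse(pts, line) <= _line_oracle_sse(pts) + 1e-9

    def test_direction_is_unit_and_canonical(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(6, 2)) * [1, 30]
            d = fit_line(pts).direction
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)
            larger = d[np.argmax(np.abs(d))]
            assert larger > 0


class TestBisector:
    def test_parallel_vertical_lines_bisect_midway(self):
        a = Line2D.from_point_direction((0, 0), (0, 1))
        b = Line2D.from_point_direction((10, 0), (0, 1))
        mid = bisector(a, b)
        assert mid.direction == pytest.approx((0, 1), abs=1e-12)
        assert mid.anchor == pytest.approx((5, 0), abs=1e-12)

    def test_symmetric_tilt_bisects_to_vertical(self):
        t = np.radians(10.0)
        a = Line2D.from_point_direction((0, 0), (np.sin(t), np.cos(t)))
        b = Line2D.from_point_direction((0, 0), (-np.sin(t), np.cos(t)))
        mid = bisector(a, b)
        assert mid.direction == pytest.approx((0, 1), abs=1e-12)
        assert mid.distance_to((0, 123.0)) < 1e-12

    def test_bisector_points_equidistant_from_both_lines(self, rng):
        for _ in range(20):
            a = Line2D.from_point_direction(rng.normal(size=2) * 10,
                                            rng.normal(size=2))
            b = Line2D.from_point_direction(rng.normal(size=2) * 10,
                                            rng.normal(size=2))
            mid = bisector(a, b)
            for t in (-50.0, 0.0, 50.0):
                p = mid.anchor + t * mid.direction
                assert a.distance_to(p) == pytest.approx(b.distance_to(p),
                                                         abs=1e-8)


class TestFitCircle:
    def test_unit_circle_from_cardinal_points(self):
        fit = fit_circle([(1, 0), (0, 1), (-1, 0), (0, -1)])
        assert fit.center == pytest.approx((0, 0), abs=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_residual < 1e-12

    def test_exact_six_point_circle_recovered(self):
        ang = np.radians(np.arange(6) * 60.0)
        pts = np.array([5.0, -3.0]) + 12.0 * np.column_stack(
            [np.cos(ang), np.sin(ang)])
        fit = fit_circle(pts)
        assert fit.center == pytest.approx((5.0, -3.0), abs=1e-9)
        assert fit.radius == pytest.approx(12.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_collinear_points_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_noisy_partial_arc_matches_nelder_mead_oracle(self, rng):
        """Geometric refinement reaches the direct-optimisation optimum on
        noisy 6-point data (radius 40, sigma 0.5 px radial noise)."""
        for _ in range(20):
            ang = rng.uniform(0, 2 * np.pi, 6)
            radii = 40.0 + rng.normal(0, 0.5, 6)
            pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
            fit = fit_circle(pts)
            start = np.array([fit.center[0] + 0.3, fit.center[1] - 0.3,
                              fit.radius + 0.5])
            oracle_x, oracle_sse = _circle_oracle(pts, start)
            assert geometric_sse(pts, fit) <= oracle_sse + 1e-8
            assert fit.center == pytest.approx(oracle_x[:2], abs=1e-4)

    def test_matches_skimage_circle_model_on_exact_data(self):
        pytest.importorskip("skimage")
        from skimage.measure import CircleModel

        ang = np.radians(np.arange(8) * 45.0 + 10.0)
        pts = np.array([2.0, 7.0]) + 9.0 * np.column_stack(
            [np.cos(ang), np.sin(ang)])
        fit = fit_circle(pts)
        if hasattr(CircleModel, "from_estimate"):
            model = CircleModel.from_estimate(pts)
            center, radius = model.center, model.radius
        else:  # older scikit-image
            model = CircleModel()
            assert model.estimate(pts)
            center, radius = model.params[:2], model.params[2]
        assert fit.center == pytest.approx(center, abs=1e-9)
        assert fit.radius == pytest.approx(radius, abs=1e-9)


class TestCalibration:
    @pytest.mark.parametrize("radius_px, expected", [(50.0, 0.254), (25.4, 0.5)])
    def test_sphere_radius_sets_scale(self, radius_px, expected):
        ang = np.radians(np.arange(5) * 72.0)
        pts = radius_px * np.column_stack([np.cos(ang), np.sin(ang)])
        assert calibrate(pts).mm_per_px == pytest.approx(expected, abs=1e-12)

    def test_doubling_coordinates_halves_scale(self):
        ang = np.radians(np.arange(5) * 72.0)
        pts = 40.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        assert calibrate(2 * pts).mm_per_px == pytest.approx(
            calibrate(pts).mm_per_px / 2, rel=1e-12)


def _symmetric_set(head_x=25.0, scale=1.0, mm_per_px=1.0):
    """Hand-built image: vertical cortices at x = +/-10, head centre on x=head_x."""
    points = []
    for x, role in ((-10.0, "medial_cortex"), (10.0, "lateral_cortex")):
        for y in np.linspace(0, 40, 5):
            points.append(("%s" % role, x, y))
    ang = np.radians(np.arange(6) * 60.0)
    for dx, dy in zip(8.0 * np.cos(ang), 8.0 * np.sin(ang)):
        points.append(("head", head_x + dx, 60.0 + dy))
    sphere_r = 25.4 / (2.0 * mm_per_px)
    ang = np.radians(np.arange(5) * 72.0)
    for dx, dy in zip(sphere_r * np.cos(ang), sphere_r * np.sin(ang)):
        points.append(("calibration", 120.0 + dx, 120.0 + dy))
    lm = [LandmarkPoint("S1", "img", 0.0, role, scale * x, scale * y)
          for role, x, y in points]
    return LandmarkSet("S1", "img", 0.0, tuple(lm))


class TestMeasureOffset:
    def test_symmetric_cortices_give_axis_midline_offset(self):
        m = measure_offset(_symmetric_set(head_x=25.0, mm_per_px=1.0))
        assert m.offset_mm == pytest.approx(25.0, abs=1e-9)
        # shaft axis is the mirror line of the two cortical point sets
        assert m.shaft_axis.distance_to((0.0, 999.0)) < 1e-9

    def test_offset_linear_in_calibration_scale(self):
        m = measure_offset(_symmetric_set(head_x=25.0, mm_per_px=0.5))
        assert m.offset_mm == pytest.approx(12.5, abs=1e-9)

    def test_scale_equivariance_pixel_zoom_cancels(self):
        base = measure_offset(_symmetric_set()).offset_mm
        zoomed = measure_offset(_symmetric_set(scale=3.7)).offset_mm
        assert zoomed == pytest.approx(base, rel=1e-12)

    @given(angle=st.floats(-np.pi, np.pi),
           tx=st.floats(-500, 500), ty=st.floats(-500, 500))
    def test_rigid_motion_invariance(self, angle, tx, ty):
        """Rotating/translating every landmark together leaves offset_mm fixed."""
        base = _symmetric_set(head_x=21.0)
        c, s = np.cos(angle), np.sin(angle)
        moved = tuple(
            LandmarkPoint(p.specimen_id, p.image_id, p.rotation_deg, p.role,
                          c * p.x_px - s * p.y_px + tx,
                          s * p.x_px + c * p.y_px + ty)
            for p in base.points
        )
        moved_set = LandmarkSet("S1", "img", 0.0, moved)
        assert measure_offset(moved_set).offset_mm == pytest.approx(
            measure_offset(base).offset_mm, rel=1e-9, abs=1e-9)

    def test_noiseless_projection_reproduces_ground_truth(self):
        model = FemurModel3D(true_offset_mm=41.3, offset_plane_deg=-7.0)
        for angle in (-30.0, -8.0, 0.0, 4.0, 30.0):
            lm, truth = project(model, angle)
            assert measure_offset(lm).offset_mm == pytest.approx(
                truth.noiseless_offset_mm, abs=1e-6)

    def test_missing_role_is_a_validation_error(self):
        base = _symmetric_set()
        headless = tuple(p for p in base.points if p.role != "head")
        from femoffset import ValidationError

        with pytest.raises(ValidationError, match="head"):
            measure_offset(LandmarkSet("S1", "img", 0.0, headless))
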
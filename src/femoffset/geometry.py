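"""Femoral-offset measurement from one annotated radiograph.

The measurement follows the landmark protocol used for fluoroscopic offset
assessment:

1. fit straight lines to the medial and lateral cortical border points of the
   proximal shaft (total least squares — the borders are near-vertical, where
   ordinary y-on-x regression is ill-conditioned);
2. take the bisector of the two cortical lines as the proximal femoral shaft
   axis;
3. fit a circle to the femoral-head points; its centre is the head's centre of
   rotation;
4. fit a circle to the calibration-sphere points; a sphere of known physical
   diameter (1 inch = 25.4 mm) in the plane of the femur gives the
   pixel-to-millimetre scale;
5. femoral offset = perpendicular distance from the head centre to the shaft
   axis, converted to millimetres.

All fits operate on point *sets*: the result never depends on point order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .landmarks_io import LandmarkSet

INCH_MM = 25.4  # exact

_PARALLEL_SIN_TOL = 1e-6


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points must be finite")
    return pts


@dataclass(frozen=True)
class Line2D:
    """Infinite 2-D line in canonical form.

    ``anchor`` is the point on the line closest to the origin and ``direction``
    is a unit vector whose larger-magnitude component is positive (ties broken
    toward positive y), so that two representations of the same line compare
    (almost) equal.
    """

    anchor: np.ndarray
    direction: np.ndarray

    @staticmethod
    def from_point_direction(point, direction) -> "Line2D":
        d = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0 or not np.all(np.isfinite(d)):
            raise DegenerateGeometryError("line direction must be a nonzero finite vector")
        d = d / norm
        # sign canonicalization: larger-|component| positive, tie -> +y
        if abs(d[0]) > abs(d[1]):
            if d[0] < 0:
                d = -d
        elif d[1] < 0:
            d = -d
        p = np.asarray(point, dtype=float)
        anchor = p - np.dot(p, d) * d
        return Line2D(anchor=anchor, direction=d)

    def distance_to(self, point) -> float:
        """Perpendicular distance from ``point`` to the line."""
        p = np.asarray(point, dtype=float) - self.anchor
        return abs(p[0] * self.direction[1] - p[1] * self.direction[0])


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: centre, radius and RMS of the geometric residuals."""

    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale derived from the in-plane calibration sphere."""

    mm_per_px: float
    sphere_fit: CircleFit
    sphere_diameter_mm: float = INCH_MM


@dataclass(frozen=True)
class OffsetMeasurement:
    """Femoral offset measured on one radiograph, with its intermediate fits."""

    specimen_id: str
    image_id: str
    rotation_deg: float
    shaft_axis: Line2D
    head_fit: CircleFit
    calibration: Calibration
    offset_mm: float


def fit_line(points: Iterable) -> Line2D:
    """Total-least-squares line through >= 2 distinct points.

    The returned line is the first principal axis through the centroid, i.e.
    it minimises the sum of squared *orthogonal* distances.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValidationError(f"fit_line needs >= 2 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.max(np.abs(centered)) < 1e-12:
        raise DegenerateGeometryError("all points coincident; line undefined")
    # first right-singular vector = direction of maximal variance
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return Line2D.from_point_direction(centroid, vt[0])


def orthogonal_sse(points, line: Line2D) -> float:
    """Sum of squared perpendicular distances of ``points`` to ``line``."""
    pts = _as_points(points) - line.anchor
    d = pts[:, 0] * line.direction[1] - pts[:, 1] * line.direction[0]
    return float(np.dot(d, d))


def bisector(a: Line2D, b: Line2D) -> Line2D:
    """Bisector of the acute angle between two lines.

    Directions are sign-harmonised (``b`` flipped if it opposes ``a``) before
    averaging, so the bisector of the two near-parallel cortical lines points
    along the shaft.  Intersecting lines are anchored at their intersection;
    (near-)parallel lines at the midpoint of the two canonical anchors, which
    for parallel cortices is the exact mid-line.
    """
    ua, ub = a.direction, b.direction
    if float(np.dot(ua, ub)) < 0:
        ub = -ub
    cross = float(ua[0] * ub[1] - ua[1] * ub[0])
    if abs(cross) < _PARALLEL_SIN_TOL:
        anchor = (a.anchor + b.anchor) / 2.0
        return Line2D.from_point_direction(anchor, ua)
    # intersection: a.anchor + t*ua = b.anchor + s*ub
    rhs = b.anchor - a.anchor
    t = (rhs[0] * ub[1] - rhs[1] * ub[0]) / cross
    anchor = a.anchor + t * ua
    return Line2D.from_point_direction(anchor, ua + ub)


def _kasa_fit(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit: linear least squares on the implicit form."""
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic circle fit collapsed (non-positive radius)")
    return center, float(np.sqrt(r2))


def fit_circle(points: Iterable, refine: bool = True, max_iter: int = 100) -> CircleFit:
    """Least-squares circle through >= 3 non-collinear points.

    A Kåsa algebraic fit provides the initial estimate; Gauss–Newton iterations
    on the geometric objective sum((|p - c| - r)^2) then remove the algebraic
    bias, which matters for the few-point partial arcs a rater marks.  The
    reported ``rms_residual`` always comes from the geometric residuals of the
    returned circle.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValidationError(f"fit_circle needs >= 3 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    # collinear (or coincident) points leave the circle undefined
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(1.0, sv[0]):
        raise DegenerateGeometryError("points are (near-)collinear; circle undefined")
    center, radius = _kasa_fit(pts)
    if refine:
        for _ in range(max_iter):
            diff = pts - center
            dist = np.linalg.norm(diff, axis=1)
            if np.any(dist < 1e-12):
                break  # a data point sits on the centre; keep current estimate
            res = dist - radius
            # Jacobian of residuals wrt (cx, cy, r)
            jac = np.column_stack([-diff[:, 0] / dist, -diff[:, 1] / dist,
                                   -np.ones(len(pts))])
            step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
            center = center + step[:2]
            radius = radius + step[2]
            if np.linalg.norm(step) < 1e-13 * (1.0 + radius):
                break
    dist = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    if radius <= 0:
        raise DegenerateGeometryError("circle fit produced non-positive radius")
    return CircleFit(center=np.asarray(center, dtype=float), radius=float(radius),
                     rms_residual=rms)


def geometric_sse(points, fit: CircleFit) -> float:
    """Sum of squared radial residuals of ``points`` about ``fit``."""
    pts = _as_points(points)
    dist = np.linalg.norm(pts - fit.center, axis=1)
    return float(np.sum((dist - fit.radius) ** 2))


def calibrate(sphere_points: Iterable, sphere_diameter_mm: float = INCH_MM) -> Calibration:
    """Pixel-to-mm scale from the calibration-sphere rim points."""
    if sphere_diameter_mm <= 0:
        raise ValidationError("sphere_diameter_mm must be positive")
    fit = fit_circle(sphere_points)
    return Calibration(
        mm_per_px=sphere_diameter_mm / (2.0 * fit.radius),
        sphere_fit=fit,
        sphere_diameter_mm=sphere_diameter_mm,
    )


def measure_offset(
    landmark_set: LandmarkSet, calibration: Optional[Calibration] = None
) -> OffsetMeasurement:
    """Measure femoral offset (mm) on one annotated radiograph.

    When ``calibration`` is ``None`` the set must carry its own
    calibration-sphere points.  Offset is reported unsigned (a distance).
    """
    landmark_set.require_roles(("medial_cortex", "lateral_cortex", "head"))
    if calibration is None:
        landmark_set.require_roles(("calibration",))
        calibration = calibrate(landmark_set.role_xy("calibration"))
    medial = fit_line(landmark_set.role_xy("medial_cortex"))
    lateral = fit_line(landmark_set.role_xy("lateral_cortex"))
    axis = bisector(medial, lateral)
    head = fit_circle(landmark_set.role_xy("head"))
    offset_mm = axis.distance_to(head.center) * calibration.mm_per_px
    return OffsetMeasurement(
        specimen_id=landmark_set.specimen_id,
        image_id=landmark_set.image_id,
        rotation_deg=landmark_set.rotation_deg,
        shaft_axis=axis,
        head_fit=head,
        calibration=calibration,
        offset_mm=float(offset_mm),
    )


def measure_all(sets: Iterable[LandmarkSet]) -> list[OffsetMeasurement]:
    """Measure every radiograph, each with its own in-image calibration."""
    return [measure_offset(s) for s in sets]
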
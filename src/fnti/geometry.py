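"""Landmark geometry for hip morphometry on ventrodorsal hip-extended views.

All constructions live in image coordinates (origin top-left, y pointing
down); units are arbitrary but must be uniform within one image.  The
quantities that leave this module — the femoral neck thickness index (FNTi)
and the Norberg angle — are unit-free, so no pixel-spacing calibration is
required.

The femoral head diameter (FHd) is the diameter of a circle fitted to
landmarks on the femoral head margin.  The femoral neck thickness (FNT) is
the minimal separation between the proximal and distal neck-margin
polylines.  FNTi = FNT / FHd.  The Norberg angle is measured at a femoral
head centre between the ray to the contralateral head centre and the ray to
the ipsilateral effective cranial acetabular rim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


class GeometryError(ValueError):
    """Degenerate or invalid landmark geometry."""


def _as_points(points, min_points: int, what: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError(f"{what}: expected an (n, 2) array of points")
    if arr.shape[0] < min_points:
        raise GeometryError(f"{what}: need at least {min_points} points, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{what}: non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (y-axis pointing down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError("Point2D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Circle:
    """A circle; ``diameter`` of the head circle is the FHd measurement."""

    centre: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise GeometryError("Circle radius must be positive and finite")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class Margin:
    """One femoral-neck margin traced as an ordered polyline (>= 2 vertices)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, 2, "Margin")
        steps = np.diff(self.points, axis=0)
        if np.any(np.hypot(steps[:, 0], steps[:, 1]) == 0.0):
            raise GeometryError("Margin: consecutive points must not coincide")

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1


@dataclass
class HipAnnotation:
    """All landmarks for one hip on one image.

    ``contra_head_centre`` (centre of the other hip's femoral head) is only
    needed for the Norberg angle and may be absent.
    """

    dog_id: str
    side: str
    head_boundary: np.ndarray
    proximal_margin: Margin
    distal_margin: Margin
    rim_point: Point2D
    contra_head_centre: Optional[Point2D] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")
        self.head_boundary = _as_points(self.head_boundary, 3, "head_boundary")
        _check_not_collinear(self.head_boundary, "head_boundary")


@dataclass
class HipMeasurement:
    """Derived scalars for one hip measured by one examiner in one session."""

    dog_id: str
    side: str
    examiner: str
    session: str
    fnt: float
    fhd: float
    fnti: float
    na: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fnt <= 0 or self.fhd <= 0 or self.fnti <= 0:
            raise GeometryError("fnt, fhd and fnti must be positive")


def _check_not_collinear(points: np.ndarray, what: str) -> None:
    centred = points - points.mean(axis=0)
    # second singular value ~ spread off the best-fit line
    sv = np.linalg.svd(centred, compute_uv=False)
    scale = max(sv[0], 1.0)
    if sv[1] <= 1e-10 * scale:
        raise GeometryError(f"{what}: points are (nearly) collinear")


def fit_circle(points, method: str = "kasa") -> Circle:
    """Fit a circle to boundary landmarks.

    ``method="kasa"`` is the algebraic least-squares fit (minimise
    sum((x^2 + y^2 + D x + E y + F)^2), closed form); for exactly three
    non-collinear points it returns the circumcircle.  ``method="geometric"``
    refines the Kåsa solution by minimising the sum of squared orthogonal
    distances to the circle.
    """
    pts = _as_points(points, 3, "fit_circle")
    _check_not_collinear(pts, "fit_circle")
    x, y = pts[:, 0], pts[:, 1]
    # shift to the centroid for conditioning
    x0, y0 = x.mean(), y.mean()
    u, v = x - x0, y - y0
    A = np.column_stack([u, v, np.ones_like(u)])
    rhs = -(u**2 + v**2)
    (D, E, F), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx**2 + cy**2 - F
    if r2 <= 0:
        raise GeometryError("fit_circle: degenerate configuration (non-positive radius)")
    cx, cy, r = cx + x0, cy + y0, math.sqrt(r2)

    if method == "geometric":

        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        sol = least_squares(resid, x0=[cx, cy, r])
        cx, cy, r = sol.x
        if r <= 0:
            raise GeometryError("fit_circle: geometric refit collapsed")
    elif method != "kasa":
        raise ValueError(f"unknown circle fit method {method!r}")
    return Circle(Point2D(cx, cy), r)


def _point_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(1.0, max(0.0, t))
    q = a + t * ab
    return float(np.hypot(*(p - q))), q

def _segments_intersect(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    if ((o1 > 0) != (o2 > 0)) and ((o3 > 0) != (o4 > 0)):
        return True
    return False

def _segment_segment(a, b, c, d) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between segments ab and cd with the realizing points."""
    if _segments_intersect(a, b, c, d):
        # crossing point: solve for the intersection
        r, s = b - a, d - c
        denom = r[0] * s[1] - r[1] * s[0]
        t = ((c[0] - a[0]) * s[1] - (c[1] - a[1]) * s[0]) / denom
        q = a + t * r
        return 0.0, q, q
    best = None
    for p, (u, v), flip in ((c, (a, b), True), (d, (a, b), True), (a, (c, d), False), (b, (c, d), False)):
        dist, q = _point_segment(p, u, v)
        pair = (q, p) if flip else (p, q)
        if best is None or dist < best[0]:
            best = (dist, pair[0], pair[1])
    return best


def minimal_neck_thickness(
    proximal: Margin,
    distal: Margin,
    axis_constraint: Optional[float] = None,
) -> tuple[float, Point2D, Point2D]:
    """Minimal separation between the two neck-margin polylines.

    Returns the smallest Euclidean distance between any point of the proximal
    polyline and any point of the distal polyline (segment-to-segment, not
    vertex-only) together with the realizing point pair — the radiographic
    rule of joining the two closest points between the margins.

    ``axis_constraint`` (degrees) optionally excludes candidate chords whose
    direction deviates from the perpendicular to the estimated neck axis by
    more than the tolerance, honouring the convention that the thickness
    chord runs roughly perpendicular to the anatomical neck axis.  The neck
    axis is estimated as the mean of the two margins' end-to-end directions.

    Ties are broken toward the smallest (proximal segment index, distal
    segment index) pair, so output is deterministic.
    """
    P, Q = proximal.points, distal.points

    perp = None
    if axis_constraint is not None:
        d1 = P[-1] - P[0]
        d2 = Q[-1] - Q[0]
        if np.dot(d1, d2) < 0:
            d2 = -d2
        axis = d1 / np.hypot(*d1) + d2 / np.hypot(*d2)
        norm = np.hypot(*axis)
        if norm == 0:
            raise GeometryError("axis_constraint: margin directions cancel, axis undefined")
        axis /= norm
        perp = np.array([-axis[1], axis[0]])

    best = None
    for i in range(len(P) - 1):
        for j in range(len(Q) - 1):
            dist, pp, pq = _segment_segment(P[i], P[i + 1], Q[j], Q[j + 1])
            if dist == 0.0:
                raise GeometryError("neck margins intersect; annotation is invalid")
            if perp is not None:
                chord = pq - pp
                cosang = abs(np.dot(chord, perp)) / np.hypot(*chord)
                dev = math.degrees(math.acos(min(1.0, cosang)))
                if dev > axis_constraint:
                    continue
            if best is None or dist < best[0]:
                best = (dist, pp, pq)
    if best is None:
        raise GeometryError(
            "no candidate chord satisfies the axis constraint; "
            "loosen the tolerance or pass axis_constraint=None"
        )
    return best[0], Point2D(*best[1]), Point2D(*best[2])


def compute_fnti(fnt: float, fhd: float) -> float:
    """Femoral neck thickness index: FNT divided by FHd, at full precision.

    Display rounding (0.91 vs 0.911) is the caller's concern.
    """
    if not (math.isfinite(fnt) and math.isfinite(fhd)):
        raise GeometryError("compute_fnti: inputs must be finite")
    if fnt <= 0 or fhd <= 0:
        raise GeometryError("compute_fnti: fnt and fhd must be positive")
    return fnt / fhd


def norberg_angle(head_centre: Point2D, contra_centre: Point2D, rim_point: Point2D) -> float:
    """Norberg angle in degrees.

    The unsigned angle at ``head_centre`` between the ray toward the
    contralateral femoral head centre and the ray toward the ipsilateral
    effective cranial acetabular rim.  Invariant under translation, rotation,
    uniform scaling and mirroring, so left and right hips share one code
    path.
    """
    c = head_centre.as_array()
    u = contra_centre.as_array() - c
    v = rim_point.as_array() - c
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise GeometryError("norberg_angle: coincident landmark points")
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = float(np.dot(u, v))
    ang = math.degrees(math.atan2(cross, dot))
    # keep the result inside [0, 180)
    return math.nextafter(180.0, 0.0) if ang >= 180.0 else ang


def measure_hip(
    annotation: HipAnnotation,
    examiner: str,
    session: str,
    circle_method: str = "kasa",
    axis_constraint: Optional[float] = None,
) -> HipMeasurement:
    """Measure FNT, FHd, FNTi and (when possible) the Norberg angle."""
    try:
        head = fit_circle(annotation.head_boundary, method=circle_method)
        fnt, _, _ = minimal_neck_thickness(
            annotation.proximal_margin, annotation.distal_margin, axis_constraint
        )
        na = None
        if annotation.contra_head_centre is not None:
            na = norberg_angle(head.centre, annotation.contra_head_centre, annotation.rim_point)
        return HipMeasurement(
            dog_id=annotation.dog_id,
            side=annotation.side,
            examiner=examiner,
            session=session,
            fnt=fnt,
            fhd=head.diameter,
            fnti=compute_fnti(fnt, head.diameter),
            na=na,
        )
    except GeometryError as err:
        raise GeometryError(
            f"hip {annotation.dog_id}/{annotation.side}: {err}"
        ) from err
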
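"""Planar geometry primitives for radiographic landmark measurements.

Coordinate convention (shared by every module): 0-based pixel coordinates,
``x`` increases rightward (columns), ``y`` increases downward (rows), so
superior anatomy has *smaller* y.  Pixel centers sit at integer coordinates.
All quantities are continuous; angles are reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .errors import InvalidGeometryError

#: Points closer than this (in pixels) are treated as coincident.
COINCIDENCE_TOL = 1e-9


class _Vertical:
    """Singleton marker for the slope of a vertical line."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "VERTICAL"


#: Returned by :func:`slope` for vertical lines instead of a raw infinity.
VERTICAL = _Vertical()

Slope = Union[float, _Vertical]


@dataclass(frozen=True)
class Point:
    """A continuous image-plane point (x = column, y = row, y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point coordinates ({self.x}, {self.y})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Line:
    """An infinite line through two distinct points."""

    p: Point
    q: Point

    def __post_init__(self) -> None:
        if self.p.distance_to(self.q) <= COINCIDENCE_TOL:
            raise InvalidGeometryError("line requires two distinct points")


def slope(line: Line) -> Slope:
    """Slope dy/dx of a line, or :data:`VERTICAL` when dx is below tolerance."""
    dx = line.q.x - line.p.x
    if abs(dx) <= COINCIDENCE_TOL:
        return VERTICAL
    return (line.q.y - line.p.y) / dx


def angle_at_vertex(vertex: Point, p1: Point, p2: Point) -> float:
    """Angle in degrees, in [0, 180], between rays vertex->p1 and vertex->p2.

    Computed from the two-argument arctangent of the cross and dot products
    of the direction vectors, which is well defined for vertical rays and
    agrees with the classical two-slope formula
    ``atan|(m1 - m2) / (1 + m1 m2)|`` wherever both slopes are finite and the
    angle is acute.

    Raises
    ------
    InvalidGeometryError
        If either ray endpoint coincides with the vertex.
    """
    v1x, v1y = p1.x - vertex.x, p1.y - vertex.y
    v2x, v2y = p2.x - vertex.x, p2.y - vertex.y
    if math.hypot(v1x, v1y) <= COINCIDENCE_TOL or math.hypot(v2x, v2y) <= COINCIDENCE_TOL:
        raise InvalidGeometryError("ray endpoint coincides with the vertex")
    cross = v1x * v2y - v1y * v2x
    dot = v1x * v2x + v1y * v2y
    return math.degrees(math.atan2(abs(cross), dot))


def angle_between_slopes(m1: float, m2: float) -> float:
    """Acute angle in degrees between two lines given by finite slopes.

    The textbook formula ``atan|(m1 - m2) / (1 + m1 m2)|``.  Kept as an
    independent cross-check for :func:`angle_at_vertex`; it is singular for
    perpendicular lines (``1 + m1 m2 = 0``) and cannot represent vertical
    lines, which is why the vector form is the production path.
    """
    denom = 1.0 + m1 * m2
    if abs(denom) <= COINCIDENCE_TOL:
        return 90.0
    return math.degrees(math.atan(abs((m1 - m2) / denom)))


def perpendicular_distance(point: Point, line: Line) -> float:
    """Euclidean distance from a point to an infinite line, in pixels."""
    dx = line.q.x - line.p.x
    dy = line.q.y - line.p.y
    length = math.hypot(dx, dy)
    # Line.__post_init__ guarantees length > COINCIDENCE_TOL.
    return abs(dx * (point.y - line.p.y) - dy * (point.x - line.p.x)) / length


def midpoint(a: Point, b: Point) -> Point:
    return Point((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)
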
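"""Core measurement geometry.

Pipeline per vertebra: outer contour -> convex hull -> simple polygon with
3 or 4 vertices -> edge midpoints -> measurement-edge selection between
adjacent vertebrae -> extraction of contour points near the selected edge
(axis-aligned boxes keyed on the edge endpoints and midpoint, with a small
margin) -> least-squares line -> angle between the two fitted lines via the
tangent addition theorem, tan(theta) = (a - b) / (1 + a*b), evaluated in
direction-vector form so that perpendicular and vertical lines are finite.

All angles are in degrees and refer to *undirected* lines, folded into the
principal interval (-90, 90].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, UnmeasurableEdgeError

logger = logging.getLogger(__name__)

#: Default half-width, in pixels, of the contour band around a measurement
#: edge.  Two pixels admit rasterization jitter without capturing the
#: lateral walls of the vertebral body.
DEFAULT_BAND_MARGIN = 2.0


def fold_angle(deg: float) -> float:
    """Fold an angle into the principal interval (-90, 90] for undirected lines."""
    d = deg % 180.0
    if d > 90.0:
        d -= 180.0
    return d


@dataclass(frozen=True)
class EdgeSegment:
    """One side of an approximating polygon, endpoints normalized x1 <= x2.

    ``(x1, y1)`` is the left endpoint, ``(x2, y2)`` the right one; for a
    vertical side the upper endpoint (smaller y) comes first.  The midpoint
    ``(x_m, y_m)`` is the arithmetic mean of the endpoints.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    @staticmethod
    def from_points(p, q) -> "EdgeSegment":
        (px, py), (qx, qy) = p, q
        if (px, py) > (qx, qy):
            px, py, qx, qy = qx, qy, px, py
        return EdgeSegment(float(px), float(py), float(qx), float(qy))

    @property
    def x_m(self) -> float:
        return 0.5 * (self.x1 + self.x2)

    @property
    def y_m(self) -> float:
        return 0.5 * (self.y1 + self.y2)

    @property
    def midpoint(self) -> tuple[float, float]:
        return (self.x_m, self.y_m)

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def angle_deg(self) -> float:
        return fold_angle(math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1)))


@dataclass
class ContourBand:
    """Contour points selected near a measurement edge."""

    verts_x: np.ndarray
    verts_y: np.ndarray
    side: str  # "upper", "lower" or "perpendicular"

    def __len__(self) -> int:
        return len(self.verts_x)


@dataclass(frozen=True)
class FittedLine:
    """A least-squares line; ``direction`` is the unit vector fallback
    representation that stays finite for vertical lines."""

    slope: float  # dy/dx in image coordinates; +-inf when vertical
    intercept: float  # pixels; nan when vertical
    direction: tuple[float, float]  # unit vector, dx > 0, or (0, 1)

    @property
    def angle_deg(self) -> float:
        return fold_angle(math.degrees(math.atan2(self.direction[1], self.direction[0])))

    @staticmethod
    def from_slope(slope: float, intercept: float = 0.0) -> "FittedLine":
        if math.isinf(slope):
            return FittedLine(slope, math.nan, (0.0, 1.0))
        n = math.hypot(1.0, slope)
        return FittedLine(slope, intercept, (1.0 / n, slope / n))


# ---------------------------------------------------------------------------
# hull and polygon approximation


def convex_hull(contour: np.ndarray) -> np.ndarray:
    """Convex hull of a contour; vertices are a subset of the contour points.

    Raises :class:`DegenerateGeometryError` when all points are collinear.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate contour: {exc}") from exc
    return pts[hull.vertices]


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2-vectors (v may be an (N,2) array)."""
    v = np.asarray(v, dtype=float)
    return u[0] * v[..., 1] - u[1] * v[..., 0]


def _point_line_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    n = np.hypot(*ab)
    if n == 0:
        return np.hypot(*(pts - a).T)
    return np.abs(_cross2(ab, pts - a)) / n


def _dp_open(pts: np.ndarray, eps: float) -> list[int]:
    """Douglas-Peucker on an open chain; returns kept indices incl. endpoints."""
    keep = {0, len(pts) - 1}
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        seg = pts[i + 1 : j]
        d = _point_line_distance(seg, pts[i], pts[j])
        k = int(np.argmax(d))
        if d[k] > eps:
            m = i + 1 + k
            keep.add(m)
            stack.append((i, m))
            stack.append((m, j))
    return sorted(keep)


def _simplify_closed(pts: np.ndarray, eps: float) -> np.ndarray:
    """Douglas-Peucker on a closed ring, anchored at the farthest vertex pair."""
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if i > j:
        i, j = j, i
    ring = np.arange(n)
    chain1 = ring[i : j + 1]
    chain2 = np.concatenate([ring[j:], ring[: i + 1]])
    k1 = [chain1[k] for k in _dp_open(pts[chain1], eps)]
    k2 = [chain2[k] for k in _dp_open(pts[chain2], eps)]
    kept = sorted(set(k1) | set(k2))
    return pts[kept]


def approximate_polygon(hull: np.ndarray, max_vertices: int = 4) -> np.ndarray:
    """Approximate a convex hull by a simple polygon with 3 or 4 vertices.

    The simplification tolerance is found by binary search so that the
    vertex count first reaches ``max_vertices`` (default 4); 3 is used only
    when no tolerance yields exactly 4.  ``max_vertices=3`` requests the
    triangle form directly, which is the stable choice for the triangular
    C1 ring where a fourth vertex would split the long posterior side.
    Output vertices are a subset of the hull's vertices, so the polygon is
    convex and inscribed in the hull.
    """
    if max_vertices not in (3, 4):
        raise ValueError("max_vertices must be 3 or 4")
    pts = np.asarray(hull, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("polygon approximation needs >= 3 hull vertices")
    if len(pts) == 3:
        return pts.copy()
    diam = math.sqrt(
        float(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1).max())
    )
    lo, hi = 0.0, diam
    best4: Optional[np.ndarray] = None
    best3: Optional[np.ndarray] = None
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        cand = _simplify_closed(pts, mid)
        c = len(cand)
        if c > max_vertices:
            lo = mid
        else:
            hi = mid
            if c == 4:
                best4 = cand
            elif c == 3 and best3 is None:
                best3 = cand
    if max_vertices == 4 and best4 is not None:
        return best4
    if best3 is not None:
        return best3
    if best4 is not None:
        return best4
    # vertex count jumped past both 3 and 4: fall back to the anchor pair
    # plus the point of maximal deviation on each side of the anchor line.
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    a, b = pts[min(i, j)], pts[max(i, j)]
    cross = _cross2(b - a, pts - a)
    dist = _point_line_distance(pts, a, b)
    picks = [min(i, j)]
    left = np.where(cross > 0)[0]
    if left.size:
        picks.append(int(left[np.argmax(dist[left])]))
    picks.append(max(i, j))
    right = np.where(cross < 0)[0]
    if right.size:
        picks.append(int(right[np.argmax(dist[right])]))
    picks_sorted = sorted(set(picks))
    if len(picks_sorted) < 3:
        raise DegenerateGeometryError("cannot form a 3- or 4-vertex approximation")
    return pts[picks_sorted]


def edge_midpoints(poly: np.ndarray) -> list[EdgeSegment]:
    """One normalized :class:`EdgeSegment` per polygon side, in ring order."""
    poly = np.asarray(poly, dtype=float)
    n = len(poly)
    return [EdgeSegment.from_points(poly[k], poly[(k + 1) % n]) for k in range(n)]


# ---------------------------------------------------------------------------
# measurement-edge selection


def select_measurement_edges(
    poly_n: np.ndarray, poly_n1: np.ndarray
) -> tuple[EdgeSegment, EdgeSegment]:
    """Pick the facing edge pair between vertebra n (cranial) and n+1.

    Returns the (edge of n, edge of n+1) pair whose midpoints are closest
    in Euclidean distance; ties are broken by midpoint x proximity.
    """
    edges_n = edge_midpoints(poly_n)
    edges_m = edge_midpoints(poly_n1)
    best = None
    best_key = None
    for en in edges_n:
        for em in edges_m:
            d = math.hypot(en.x_m - em.x_m, en.y_m - em.y_m)
            key = (d, abs(en.x_m - em.x_m))
            if best_key is None or key < best_key:
                best_key = key
                best = (en, em)
    assert best is not None
    return best


def c1_measurement_line(poly: np.ndarray) -> EdgeSegment:
    """Longest side of the C1 approximation (the posterior-arch line)."""
    edges = edge_midpoints(poly)
    lengths = [e.length for e in edges]
    mx = max(lengths)
    winners = [e for e, l in zip(edges, lengths) if math.isclose(l, mx, rel_tol=1e-12)]
    if len(winners) > 1:
        logger.warning("C1 approximation has %d equally-long sides; using the first", len(winners))
    return winners[0]


def c2_measurement_line(poly: np.ndarray, facing: str = "left") -> EdgeSegment:
    """Side to the right of the lower edge of the C2 approximation.

    The lower edge is the side whose midpoint y is maximal (y grows
    downward); among the sides sharing one of its vertices, the neighbor
    with the greater midpoint x is "right".  ``facing="right"`` flips the
    comparison for radiographs acquired with the patient facing the other
    way.
    """
    poly = np.asarray(poly, dtype=float)
    n = len(poly)
    sides = [(poly[k], poly[(k + 1) % n]) for k in range(n)]
    mids_y = [0.5 * (p[1] + q[1]) for p, q in sides]
    low = int(np.argmax(mids_y))
    neighbors = [sides[(low - 1) % n], sides[(low + 1) % n]]
    mids_x = [0.5 * (p[0] + q[0]) for p, q in neighbors]
    if facing == "left":
        pick = int(np.argmax(mids_x))
    elif facing == "right":
        pick = int(np.argmin(mids_x))
    else:
        raise ValueError(f"facing must be 'left' or 'right', got {facing!r}")
    p, q = neighbors[pick]
    return EdgeSegment.from_points(p, q)


# ---------------------------------------------------------------------------
# contour bands


def perpendicular_band(
    contour: np.ndarray, edge: EdgeSegment, margin: float = DEFAULT_BAND_MARGIN
) -> ContourBand:
    """Contour points near the edge by perpendicular distance.

    Used directly for near-vertical measurement lines and as the fallback
    when the axis-aligned extraction boxes are empty.  Points whose
    projection falls within the edge span (extended by ``margin``) and whose
    distance to the edge line is within ``margin`` of the closest such point
    are returned — i.e. the nearest boundary run, not just points within an
    absolute distance.
    """
    pts = np.asarray(contour, dtype=float)
    a = np.array([edge.x1, edge.y1])
    b = np.array([edge.x2, edge.y2])
    ab = b - a
    L = np.hypot(*ab)
    if L == 0:
        raise UnmeasurableEdgeError("zero-length measurement edge")
    t = (pts - a) @ ab / (L * L)
    dist = _point_line_distance(pts, a, b)
    in_span = (t >= -margin / L) & (t <= 1 + margin / L)
    if not np.any(in_span):
        in_span = np.ones(len(pts), dtype=bool)
    dmin = dist[in_span].min()
    sel = in_span & (dist <= dmin + margin)
    if sel.sum() < 2:
        order = np.argsort(np.where(in_span, dist, np.inf))
        sel = np.zeros(len(pts), dtype=bool)
        sel[order[:2]] = True
    band = ContourBand(pts[sel, 0].copy(), pts[sel, 1].copy(), "perpendicular")
    if len(np.unique(np.column_stack([band.verts_x, band.verts_y]), axis=0)) < 2:
        raise UnmeasurableEdgeError("fewer than 2 distinct contour points near edge")
    return band


def extract_contour_band(
    contour: np.ndarray,
    edge: EdgeSegment,
    side: str,
    margin: float = DEFAULT_BAND_MARGIN,
) -> ContourBand:
    """Extract the contour points near a measurement edge.

    ``side="upper"`` keeps points with x1 <= x <= x2 and y between the edge
    endpoints' y values (expanded by ``margin``).  ``side="lower"`` is the
    union of two boxes split at the edge midpoint: the left box bounded by
    the y values of the left endpoint and the midpoint, and the right box
    open downward from the right endpoint's y, capped at the contour's own
    maximal y.

    Because the boxes are axis-aligned, a strongly tilted edge would sweep
    in parts of the lateral walls; the box selection is therefore
    intersected with a perpendicular-distance cut at ``margin`` pixels from
    the edge line, which keeps only the boundary run the edge approximates.
    If fewer than 2 points survive, the perpendicular-distance band (the
    nearest boundary run) is used instead.
    """
    pts = np.asarray(contour, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if side == "upper":
        ylo = min(edge.y1, edge.y2) - margin
        yhi = max(edge.y1, edge.y2) + margin
        sel = (x >= edge.x1) & (x <= edge.x2) & (y >= ylo) & (y <= yhi)
    elif side == "lower":
        ylo1 = min(edge.y1, edge.y_m) - margin
        yhi1 = max(edge.y1, edge.y_m) + margin
        box1 = (x >= edge.x1) & (x <= edge.x_m) & (y >= ylo1) & (y <= yhi1)
        box2 = (x >= edge.x_m) & (x <= edge.x2) & (y >= edge.y2 - margin) & (y <= y.max())
        sel = box1 | box2
    else:
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    a = np.array([edge.x1, edge.y1])
    b = np.array([edge.x2, edge.y2])
    if edge.length > 0:
        sel = sel & (_point_line_distance(pts, a, b) <= margin)
    if sel.sum() < 2:
        return perpendicular_band(pts, edge, margin)
    return ContourBand(pts[sel, 0].copy(), pts[sel, 1].copy(), side)


def refine_edge_band(
    contour: np.ndarray, edge: EdgeSegment, margin: float = DEFAULT_BAND_MARGIN
) -> ContourBand:
    """Band extraction with the side chosen from the edge's orientation.

    Edges steeper than 45 degrees (the near-vertical C1/C2 measurement
    lines) use the perpendicular band; shallower edges use the upper or
    lower box rule depending on whether the edge midpoint lies below the
    contour centroid.
    """
    pts = np.asarray(contour, dtype=float)
    if abs(edge.y2 - edge.y1) > abs(edge.x2 - edge.x1):
        return perpendicular_band(pts, edge, margin)
    side = "lower" if edge.y_m > pts[:, 1].mean() else "upper"
    return extract_contour_band(pts, edge, side, margin)


# ---------------------------------------------------------------------------
# line fitting and angles


def _ls_line(x: np.ndarray, y: np.ndarray) -> FittedLine:
    pts = np.column_stack([x, y]) - [x.mean(), y.mean()]
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    dx, dy = (float(vt[0, 0]), float(vt[0, 1]))
    if dx < 0 or (dx == 0 and dy < 0):
        dx, dy = -dx, -dy
    if abs(dx) < 1e-12:
        return FittedLine(math.inf, math.nan, (0.0, 1.0))
    slope = dy / dx
    intercept = y.mean() - slope * x.mean()
    n = math.hypot(dx, dy)
    return FittedLine(slope, float(intercept), (dx / n, dy / n))


def _line_residuals(line: FittedLine, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx, dy = line.direction
    cx, cy = x.mean(), y.mean()
    if not math.isinf(line.slope):
        cy = line.slope * cx + line.intercept
    return np.abs(-(x - cx) * dy + (y - cy) * dx)


#: residual floor (pixels) below which no point is ever trimmed
_TRIM_FLOOR = 0.75


def fit_line(band: ContourBand) -> FittedLine:
    """Least-squares line through a contour band.

    The line is the total-least-squares principal axis of the points:
    orthogonal-distance regression treats all edge orientations alike, so
    the angle between two fitted lines is invariant under a rigid rotation
    of the scene, and near-vertical lines (C1 posterior arch, C2 posterior
    body) are as stable as horizontal endplates.  For collinear points it
    coincides with ordinary least squares.  Trimmed refits (up to 5 passes,
    against the full
    band each time) then discard points whose perpendicular residual
    exceeds three times the median residual (with a sub-pixel floor), so
    rounded-corner arcs and stray boundary points at the band ends do not
    rotate the endplate line; iteration lets the fit escape an initial
    estimate dragged toward a displaced polygon corner.
    """
    x = np.asarray(band.verts_x, dtype=float)
    y = np.asarray(band.verts_y, dtype=float)
    if len(x) < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0):
        raise DegenerateGeometryError("line fit needs >= 2 distinct points")
    line = _ls_line(x, y)
    if len(x) <= 4:
        return line
    for _ in range(5):
        res = _line_residuals(line, x, y)
        keep = res <= max(3.0 * float(np.median(res)), _TRIM_FLOOR)
        if keep.sum() < 2 or keep.sum() == len(x):
            break
        xk, yk = x[keep], y[keep]
        if np.ptp(xk) == 0 and np.ptp(yk) == 0:
            break
        new = _ls_line(xk, yk)
        converged = abs(angle_between(new, line)) < 1e-9
        line = new
        if converged:
            break
    return line


def angle_between(line1: FittedLine, line2: FittedLine) -> float:
    """Signed principal angle (degrees) from ``line2`` to ``line1``.

    Computed from direction vectors, which coincides with
    ``atan((a - b) / (1 + a*b))`` wherever that expression is defined and
    returns exactly 90 at its pole (perpendicular lines).
    """
    a1 = math.atan2(line1.direction[1], line1.direction[0])
    a2 = math.atan2(line2.direction[1], line2.direction[0])
    th = fold_angle(math.degrees(a1 - a2))
    if 90.0 - abs(th) < 1e-9:
        return 90.0  # perpendicular lines: -90 and 90 name the same angle
    return th
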
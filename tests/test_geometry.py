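import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cromkit.errors import DegenerateGeometryError, UnmeasurableEdgeError
from cromkit.geometry import (
    ContourBand,
    EdgeSegment,
    FittedLine,
    angle_between,
    approximate_polygon,
    c1_measurement_line,
    c2_measurement_line,
    convex_hull,
    edge_midpoints,
    extract_contour_band,
    fit_line,
    fold_angle,
    perpendicular_band,
    select_measurement_edges,
)


# ---------------------------------------------------------------------------
# oracles


def gift_wrap_hull(points):
    """Brute-force gift-wrapping convex hull, O(n*h)."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    while True:
        cand = pts[0] if pts[0] != hull[-1] else pts[1]
        for p in pts:
            if p == hull[-1]:
                continue
            cx = (cand[0] - hull[-1][0]) * (p[1] - hull[-1][1]) - (
                cand[1] - hull[-1][1]
            ) * (p[0] - hull[-1][0])
            d_cand = math.dist(hull[-1], cand)
            d_p = math.dist(hull[-1], p)
            if cx < 0 or (cx == 0 and d_p > d_cand):
                cand = p
        if cand == start:
            return hull
        hull.append(cand)


def exhaustive_edge_pair(poly_a, poly_b):
    """Oracle: enumerate every edge pair and minimize midpoint distance."""
    best = None
    for ea in edge_midpoints(poly_a):
        for eb in edge_midpoints(poly_b):
            d = math.hypot(ea.x_m - eb.x_m, ea.y_m - eb.y_m)
            if best is None or d < best[0] - 1e-12:
                best = (d, ea, eb)
    return best[1], best[2]


def random_convex(rng, center, scale=20.0, n=8):
    ang = np.sort(rng.uniform(0, 2 * math.pi, n))
    rad = rng.uniform(0.5, 1.0, n) * scale
    pts = np.column_stack([np.cos(ang), np.sin(ang)]) * rad[:, None] + center
    return convex_hull(pts)


# ---------------------------------------------------------------------------
# convex hull & polygon approximation


def test_hull_of_square_with_interior_point():
    contour = np.array([[0, 0], [4, 0], [4, 4], [2, 3], [0, 4]], dtype=float)
    hull = convex_hull(contour)
    assert len(hull) == 4
    assert {tuple(p) for p in hull} == {(0, 0), (4, 0), (4, 4), (0, 4)}


def test_hull_matches_gift_wrapping_oracle():
    # plus-sign shape plus random blobs
    plus = np.array(
        [[2, 0], [4, 0], [4, 2], [6, 2], [6, 4], [4, 4],
         [4, 6], [2, 6], [2, 4], [0, 4], [0, 2], [2, 2]], dtype=float
    )
    rng = np.random.default_rng(3)
    for pts in [plus] + [rng.normal(0, 10, (30, 2)).round(1) for _ in range(10)]:
        got = {tuple(p) for p in convex_hull(pts)}
        want = set(gift_wrap_hull(pts))
        assert got == want


def test_hull_of_triangle_is_identity():
    tri = np.array([[0, 0], [5, 0], [2, 7]], dtype=float)
    assert {tuple(p) for p in convex_hull(tri)} == {tuple(p) for p in tri}


def test_hull_collinear_raises():
    with pytest.raises(DegenerateGeometryError):
        convex_hull(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float))


def test_approximation_drops_collinear_midside_points():
    rect = np.array(
        [[0, 0], [3, 0], [6, 0], [6, 2], [6, 4], [3, 4], [0, 4], [0, 2]],
        dtype=float,
    )
    poly = approximate_polygon(rect)
    assert {tuple(p) for p in poly} == {(0, 0), (6, 0), (6, 4), (0, 4)}


def test_approximation_triangle_identity():
    tri = np.array([[0, 0], [5, 0], [2, 7]], dtype=float)
    np.testing.assert_array_equal(approximate_polygon(tri), tri)


@pytest.mark.parametrize("radius, tol", [(4.0, 3.0), (6.0, 3.5)])
def test_approximation_of_rounded_rectangle_recovers_corners(radius, tol):
    # 80x50 body with rounded corners: the 4 returned vertices land on the
    # corner arcs, a bounded distance from the sharp corners (the mid-arc
    # point sits r*sqrt(2 - sqrt(2)) ~ 0.77 r away)
    import shapely
    from shapely.geometry import Polygon

    w, h = 80.0, 50.0
    corners = [(0, 0), (w, 0), (w, h), (0, h)]
    rounded = (
        Polygon(corners)
        .buffer(-radius, join_style="mitre")
        .buffer(radius, join_style="round", quad_segs=6)
    )
    pts = np.asarray(shapely.segmentize(rounded, 2.0).exterior.coords)[:-1]
    poly = approximate_polygon(convex_hull(pts))
    assert len(poly) == 4
    for v in poly:
        assert min(math.dist(v, c) for c in corners) <= tol


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 10_000))
def test_approximation_always_3_or_4_vertices_and_inscribed(seed):
    rng = np.random.default_rng(seed)
    hull = random_convex(rng, center=np.zeros(2), n=rng.integers(5, 16))
    poly = approximate_polygon(hull)
    assert len(poly) in (3, 4)
    import shapely.geometry as sg

    assert sg.Polygon(poly).area <= sg.Polygon(hull).area + 1e-9
    hull_set = {tuple(p) for p in hull}
    assert all(tuple(v) in hull_set for v in poly)


# ---------------------------------------------------------------------------
# edges and midpoints


def test_edge_midpoints_of_square():
    square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
    mids = {e.midpoint for e in edge_midpoints(square)}
    assert mids == {(1.0, 0.0), (2.0, 1.0), (1.0, 2.0), (0.0, 1.0)}


def test_edge_midpoint_is_mean_of_endpoints():
    rng = np.random.default_rng(1)
    poly = random_convex(rng, center=np.array([5.0, 5.0]))
    for e in edge_midpoints(poly):
        assert e.x_m == pytest.approx((e.x1 + e.x2) / 2)
        assert e.y_m == pytest.approx((e.y1 + e.y2) / 2)
        assert e.x1 <= e.x2


def test_triangle_has_three_edges():
    tri = np.array([[0, 0], [5, 0], [2, 7]], dtype=float)
    assert len(edge_midpoints(tri)) == 3


def test_select_edges_stacked_rectangles():
    upper = np.array([[0, 0], [40, 0], [40, 30], [0, 30]], dtype=float)
    lower = np.array([[0, 42], [40, 42], [40, 72], [0, 72]], dtype=float)
    e_up, e_lo = select_measurement_edges(upper, lower)
    assert (e_up.y1, e_up.y2) == (30, 30)  # bottom edge of the upper body
    assert (e_lo.y1, e_lo.y2) == (42, 42)  # top edge of the lower body


def _rot_poly(poly, deg):
    c = poly.mean(axis=0)
    r = math.radians(deg)
    R = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
    return (poly - c) @ R.T + c


def test_select_edges_rotated_rectangles_match_oracle():
    upper = _rot_poly(np.array([[0, 0], [40, 0], [40, 30], [0, 30]], float), 10)
    lower = _rot_poly(np.array([[0, 42], [40, 42], [40, 72], [0, 72]], float), -5)
    got = select_measurement_edges(upper, lower)
    want = exhaustive_edge_pair(upper, lower)
    assert got[0].midpoint == want[0].midpoint
    assert got[1].midpoint == want[1].midpoint


def test_select_edges_triangle_over_rectangle():
    tri = np.array([[5, 0], [35, 0], [20, 28]], dtype=float)
    rect = np.array([[0, 40], [40, 40], [40, 70], [0, 70]], dtype=float)
    e_tri, e_rect = select_measurement_edges(tri, rect)
    want = exhaustive_edge_pair(tri, rect)
    assert e_tri.midpoint == want[0].midpoint
    assert (e_rect.y1, e_rect.y2) == (40, 40)


def test_c1_longest_side():
    tri = np.array([[0, 0], [4, 15], [0, 30]], dtype=float)
    e = c1_measurement_line(tri)
    assert {(e.x1, e.y1), (e.x2, e.y2)} == {(0, 0), (0, 30)}
    # a slanted side can out-measure the vertical one: longest wins by length
    tri2 = np.array([[0, 0], [4, 0], [0, 30]], dtype=float)
    e2 = c1_measurement_line(tri2)
    assert {(e2.x1, e2.y1), (e2.x2, e2.y2)} == {(4, 0), (0, 30)}


def test_c1_equilateral_tie_warns(caplog):
    s = math.sqrt(3)
    tri = np.array([[0, 0], [2, 0], [1, s]], dtype=float)
    with caplog.at_level("WARNING"):
        c1_measurement_line(tri)
    assert any("equally-long" in r.message for r in caplog.records)


def test_c2_right_of_lower_edge_square():
    square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
    e = c2_measurement_line(square)
    assert (e.x1, e.x2) == (10, 10)  # the right side


def test_c2_right_of_lower_edge_triangle():
    tri = np.array([[0, 0], [40, 0], [20, -50]], dtype=float)
    e = c2_measurement_line(tri)
    assert {(e.x1, e.y1), (e.x2, e.y2)} == {(40, 0), (20, -50)}


def test_c2_facing_flag_flips_side():
    square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
    e = c2_measurement_line(square, facing="right")
    assert (e.x1, e.x2) == (0, 0)  # the left side


# ---------------------------------------------------------------------------
# contour bands


def _dense_rect(x0, y0, w, h, step=1.0):
    xs = np.arange(x0, x0 + w, step)
    ys = np.arange(y0, y0 + h, step)
    return np.vstack(
        [
            np.column_stack([xs, np.full_like(xs, y0)]),
            np.column_stack([np.full_like(ys, x0 + w), ys]),
            np.column_stack([xs[::-1] + step, np.full_like(xs, y0 + h)]),
            np.column_stack([np.full_like(ys, x0), ys[::-1] + step]),
        ]
    )


def _band_oracle(contour, edge, side, margin=2.0):
    """Brute-force per-point check of the box rules + proximity cut."""
    out = []
    ymax = contour[:, 1].max()
    for px, py in contour:
        if side == "upper":
            ok = (
                edge.x1 <= px <= edge.x2
                and min(edge.y1, edge.y2) - margin <= py <= max(edge.y1, edge.y2) + margin
            )
        else:
            in1 = (
                edge.x1 <= px <= edge.x_m
                and min(edge.y1, edge.y_m) - margin <= py <= max(edge.y1, edge.y_m) + margin
            )
            in2 = edge.x_m <= px <= edge.x2 and edge.y2 - margin <= py <= ymax
            ok = in1 or in2
        if ok:
            a = np.array([edge.x1, edge.y1])
            d = np.array([edge.x2 - edge.x1, edge.y2 - edge.y1])
            dist = abs(d[0] * (py - a[1]) - d[1] * (px - a[0])) / np.hypot(*d)
            ok = dist <= margin
        if ok:
            out.append((px, py))
    return set(out)


@pytest.mark.parametrize("side", ["lower", "upper"])
def test_band_on_rectangle_matches_brute_force(side):
    contour = _dense_rect(10, 20, 40, 25)
    y_edge = 45 if side == "lower" else 20
    edge = EdgeSegment.from_points((10, y_edge), (50, y_edge))
    band = extract_contour_band(contour, edge, side)
    got = set(zip(band.verts_x, band.verts_y))
    assert got == _band_oracle(contour, edge, side)
    # the selected run is the horizontal side itself
    assert all(abs(y - y_edge) <= 2 for _, y in got)


def test_band_is_subset_of_contour(clean_phantom):
    flex, _, _ = clean_phantom
    contour = flex.regions[3].contour
    edge = EdgeSegment.from_points(contour[0], contour[len(contour) // 2])
    band = perpendicular_band(contour, edge)
    pts = {tuple(p) for p in contour}
    assert all((x, y) in pts for x, y in zip(band.verts_x, band.verts_y))


def test_band_fallback_on_displaced_edge():
    # corner-only contour: the extraction boxes around an edge displaced
    # 10 px inside the body are empty, so the nearest boundary run wins
    contour = np.array([[10, 20], [50, 20], [50, 45], [10, 45]], dtype=float)
    edge = EdgeSegment.from_points((10, 35), (50, 35))
    band = extract_contour_band(contour, edge, "lower")
    assert band.side == "perpendicular"
    assert len(band) >= 2
    # the bottom side (distance 10) beats the top side (distance 15)
    assert set(np.unique(band.verts_y)) == {45.0}


def test_band_error_when_too_few_points():
    tiny = np.array([[0, 0], [0.1, 0], [0, 0.1]])
    edge = EdgeSegment.from_points((100, 100), (101, 100))
    with pytest.raises(UnmeasurableEdgeError):
        perpendicular_band(np.repeat(tiny[:1], 3, axis=0) + [[0, 0], [0, 0], [0, 0]], edge)


# ---------------------------------------------------------------------------
# line fitting and angles


def test_fit_collinear_points_exact():
    band = ContourBand(np.array([0.0, 1, 2]), np.array([0.0, 1, 2]), "upper")
    line = fit_line(band)
    assert line.slope == pytest.approx(1.0)
    assert line.intercept == pytest.approx(0.0)


def test_fit_vertical_points():
    band = ContourBand(np.zeros(3), np.array([0.0, 10, 20]), "upper")
    line = fit_line(band)
    assert line.direction == (0.0, 1.0)
    assert math.isinf(line.slope)


def test_fit_noisy_line_matches_closed_form():
    rng = np.random.default_rng(11)
    x = np.linspace(0, 100, 200)
    y = 0.2 * x + 3 + rng.uniform(-0.5, 0.5, 200)
    band = ContourBand(x, y, "upper")
    line = fit_line(band)
    # closed-form total-least-squares oracle: leading eigenvector of the
    # centered covariance matrix
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    evals, evecs = np.linalg.eigh(pts.T @ pts)
    v = evecs[:, np.argmax(evals)]
    slope_tls = float(v[1] / v[0])
    assert line.slope == pytest.approx(slope_tls, abs=1e-9)
    assert abs(line.slope - 0.2) < 0.02


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (0.37, 0.37, 0.0),
        (1.0, 0.0, 45.0),
        (1.0, -1.0, 90.0),  # pole of the tangent quotient
        (0.5, -0.5, math.degrees(math.atan(4 / 3))),
    ],
)
def test_angle_between_known_slopes(a, b, expected):
    th = angle_between(FittedLine.from_slope(a), FittedLine.from_slope(b))
    assert th == pytest.approx(expected, abs=1e-9)


def test_tangent_addition_equivalence():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        a, b = rng.uniform(-5, 5, 2)
        if abs(1 + a * b) <= 1e-6:
            continue
        th = angle_between(FittedLine.from_slope(a), FittedLine.from_slope(b))
        want = math.degrees(math.atan((a - b) / (1 + a * b)))
        assert abs(th - want) < 1e-9


def test_angle_rotation_covariance():
    rng = np.random.default_rng(5)
    pts1 = np.column_stack([rng.normal(0, 10, 50)] * 2) + rng.normal(0, 0.3, (50, 2))
    pts2 = np.column_stack([np.linspace(0, 20, 40), np.linspace(0, 20, 40) * 0.3]) + rng.normal(
        0, 0.2, (40, 2)
    )
    base = angle_between(
        fit_line(ContourBand(pts1[:, 0], pts1[:, 1], "upper")),
        fit_line(ContourBand(pts2[:, 0], pts2[:, 1], "upper")),
    )
    for phi in (10.0, 37.0, -20.0):
        r = math.radians(phi)
        R = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        q1, q2 = pts1 @ R.T, pts2 @ R.T
        th = angle_between(
            fit_line(ContourBand(q1[:, 0], q1[:, 1], "upper")),
            fit_line(ContourBand(q2[:, 0], q2[:, 1], "upper")),
        )
        assert abs(th - base) < 1e-6


@settings(deadline=None, max_examples=60)
@given(st.floats(-1000, 1000))
def test_fold_angle_principal_interval(deg):
    d = fold_angle(deg)
    assert -90 < d <= 90
    # folding never changes the line: tangents agree away from the pole
    if abs(d) < 89:
        assert math.tan(math.radians(d)) == pytest.approx(
            math.tan(math.radians(deg)), rel=1e-6, abs=1e-6
        )
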
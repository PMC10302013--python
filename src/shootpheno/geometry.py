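"""Exact 2-D computational geometry over pixel-center point sets.

All shoot-shape descriptors that are not plain pixel counts reduce to four
classical primitives over the set of foreground pixel centers:

* convex hull (Andrew's monotone chain),
* maximum pairwise distance, the Feret/caliper length (rotating calipers),
* minimum-area enclosing rectangle (a side is collinear with a hull edge),
* minimum enclosing circle (Welzl's randomized incremental algorithm).

Points are ``(x, y)`` float pairs in pixel units; a single pixel is its
center, so an isolated pixel has caliper length 0.  All results are exact to
floating precision and are checked against brute-force oracles in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Circle",
    "convex_hull",
    "polygon_area",
    "polygon_perimeter",
    "caliper_length",
    "min_area_rectangle",
    "min_enclosing_circle",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Circle:
    """A circle given by center ``(cx, cy)`` and ``radius``, pixel units."""

    cx: float
    cy: float
    radius: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, p, tol: float = 1e-9) -> bool:
        return math.hypot(p[0] - self.cx, p[1] - self.cy) <= self.radius + tol


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of 2-D points")
    if pts.shape[0] == 0:
        raise ValueError("point set is empty")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull as a counter-clockwise (k, 2) vertex array.

    Monotone chain on the lexicographically sorted unique points; collinear
    points interior to an edge are excluded.  Degenerate inputs (one point,
    all collinear) return the 1- or 2-point "hull" spanning the extent.
    """
    pts = _as_points(points)
    uniq = np.unique(pts, axis=0)  # lexicographic sort on (x, y)
    n = uniq.shape[0]
    if n <= 2:
        return uniq
    pts_list = [tuple(p) for p in uniq]

    lower: list[tuple[float, float]] = []
    for p in pts_list:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= _EPS:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(pts_list):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= _EPS:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all points collinear
        return np.array([pts_list[0], pts_list[-1]])
    return np.asarray(hull)


def polygon_area(vertices) -> float:
    """Shoelace area of a simple polygon; 0 for degenerate (<3 vertices)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices) -> float:
    """Closed-polygon perimeter; for a 2-point "hull" the segment length."""
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 2:
        return 0.0
    if v.shape[0] == 2:
        return float(np.hypot(*(v[1] - v[0])))
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def caliper_length(points) -> float:
    """Maximum pairwise Euclidean distance (Feret diameter).

    Computed by rotating calipers on the hull: the diameter is attained
    between two hull vertices, and for each hull edge the farthest vertex
    advances monotonically around the hull.  Requires >= 2 distinct points.
    """
    pts = _as_points(points)
    hull = convex_hull(pts)
    k = hull.shape[0]
    if k == 1:
        raise ValueError("caliper length needs at least 2 distinct points")
    if k == 2:
        return float(np.hypot(*(hull[1] - hull[0])))

    def d2(i: int, j: int) -> float:
        dx = hull[i, 0] - hull[j, 0]
        dy = hull[i, 1] - hull[j, 1]
        return dx * dx + dy * dy

    best = 0.0
    j = 1
    for i in range(k):
        nxt = (i + 1) % k
        # advance the antipodal pointer while the triangle area keeps growing
        while True:
            jn = (j + 1) % k
            area_next = abs(_cross(hull[i], hull[nxt], hull[jn]))
            area_cur = abs(_cross(hull[i], hull[nxt], hull[j]))
            if area_next > area_cur + _EPS:
                j = jn
            else:
                break
        best = max(best, d2(i, j), d2(nxt, j))
    return math.sqrt(best)


def min_area_rectangle(points) -> tuple[np.ndarray, float]:
    """Minimum-area enclosing rectangle ``(corners, area)``.

    Rotating-calipers sweep over hull edges: some side of an optimal
    rectangle is collinear with a hull edge, so it suffices to project the
    hull onto each edge direction and its normal.  ``corners`` is a (4, 2)
    array in order; ``area`` is in px².  Collinear/singleton sets give a
    zero-area (degenerate) rectangle.
    """
    pts = _as_points(points)
    hull = convex_hull(pts)
    if hull.shape[0] == 1:
        c = np.repeat(hull, 4, axis=0)
        return c, 0.0
    if hull.shape[0] == 2:
        corners = np.array([hull[0], hull[1], hull[1], hull[0]])
        return corners, 0.0

    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    dirs = edges / lengths[:, None]

    best_area = math.inf
    best_corners = None
    for ux, uy in dirs:
        # projections onto edge direction u and normal n = (-uy, ux)
        pu = hull[:, 0] * ux + hull[:, 1] * uy
        pn = -hull[:, 0] * uy + hull[:, 1] * ux
        w = pu.max() - pu.min()
        h = pn.max() - pn.min()
        area = w * h
        if area < best_area - _EPS:
            best_area = area
            u0, u1 = pu.min(), pu.max()
            n0, n1 = pn.min(), pn.max()
            corners_un = [(u0, n0), (u1, n0), (u1, n1), (u0, n1)]
            best_corners = np.array(
                [(u * ux - n * uy, u * uy + n * ux) for u, n in corners_un]
            )
    return best_corners, float(best_area)


def _circle_from(points: list) -> Circle:
    """Exact circle through 0–3 support points."""
    if not points:
        return Circle(0.0, 0.0, 0.0)
    if len(points) == 1:
        return Circle(points[0][0], points[0][1], 0.0)
    if len(points) == 2:
        (ax, ay), (bx, by) = points
        cx, cy = (ax + bx) / 2.0, (ay + by) / 2.0
        return Circle(cx, cy, math.hypot(ax - cx, ay - cy))
    (ax, ay), (bx, by), (cx, cy) = points
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < _EPS:  # collinear support — fall back to the widest pair
        pairs = [
            _circle_from([points[0], points[1]]),
            _circle_from([points[0], points[2]]),
            _circle_from([points[1], points[2]]),
        ]
        return max(pairs, key=lambda c: c.radius)
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    return Circle(ux, uy, math.hypot(ax - ux, ay - uy))


def min_enclosing_circle(points, seed: int | None = 0) -> Circle:
    """Smallest circle containing all points (Welzl, move-to-front).

    The incremental insertion order is shuffled with ``seed`` for the
    expected-linear running time; the returned circle is deterministic in
    value (it is unique) regardless of seed, and is supported by at most
    three input points.
    """
    pts = _as_points(points)
    order = [tuple(p) for p in np.unique(pts, axis=0)]
    rng = np.random.default_rng(seed)
    rng.shuffle(order)

    circle = Circle(order[0][0], order[0][1], 0.0)
    for i, p in enumerate(order[1:], start=1):
        if circle.contains(p):
            continue
        # p must be on the boundary of the circle of order[:i+1]
        circle = _circle_from([p])
        for j, q in enumerate(order[:i]):
            if circle.contains(q):
                continue
            circle = _circle_from([p, q])
            for r in order[:j]:
                if circle.contains(r):
                    continue
                circle = _circle_from([p, q, r])
    return circle
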
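"""Exact planar geometry primitives shared by the spatial statistics.

Two primitives recur throughout the suite:

* the area of a disc (or annulus) centred at a point *inside* a rectangular
  observation window, intersected with that window — the edge correction that
  keeps CSR-normalised statistics unbiased near boundaries;
* the radius of the minimum enclosing circle (MEC) of three points — the
  "neighbourhood" size of a cell triplet.

Both are closed-form and fully vectorised.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "circle_window_area",
    "annulus_window_area",
    "mec_radius",
    "mec_radius_from_distances",
    "mec_circle",
]


def _quarter_area(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of {x²+y² ≤ r², 0 ≤ x ≤ a, 0 ≤ y ≤ b} for a, b ≥ 0.

    If the clipped corner (min(a,r), min(b,r)) lies inside the circle the
    clipped rectangle is entirely inside (the disc is convex and contains all
    four corners); otherwise split the integral at x0 = sqrt(r² − b'²).
    """
    a = np.minimum(a, r)
    b = np.minimum(b, r)
    r2 = r * r

    def G(x):  # ∫ sqrt(r² − t²) dt from 0 to x
        x = np.minimum(x, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            asin = np.arcsin(np.clip(np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0), -1.0, 1.0))
        return 0.5 * (x * np.sqrt(np.maximum(r2 - x * x, 0.0)) + r2 * asin)

    inside = a * a + b * b <= r2
    x0 = np.sqrt(np.maximum(r2 - b * b, 0.0))
    outside_area = b * x0 + G(a) - G(x0)
    return np.where(inside, a * b, outside_area)


def circle_window_area(cx, cy, radius, width: float, height: float) -> np.ndarray:
    """Area of the disc of ``radius`` centred at (cx, cy) clipped to [0,width]×[0,height].

    Centres must lie inside the window (the case that arises for cell
    centroids); broadcasting over centres and radii is supported.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    r = np.asarray(radius, dtype=float)
    if np.any(cx < 0) or np.any(cx > width) or np.any(cy < 0) or np.any(cy > height):
        raise ValueError("circle centres must lie inside the window")
    cx, cy, r = np.broadcast_arrays(cx, cy, r)
    area = (
        _quarter_area(width - cx, height - cy, r)
        + _quarter_area(cx, height - cy, r)
        + _quarter_area(cx, cy, r)
        + _quarter_area(width - cx, cy, r)
    )
    return area


def annulus_window_area(cx, cy, inner, outer, width: float, height: float) -> np.ndarray:
    """Area of the annulus [inner, outer) around (cx, cy) clipped to the window."""
    return circle_window_area(cx, cy, outer, width, height) - circle_window_area(
        cx, cy, inner, width, height
    )


def mec_radius_from_distances(d12, d13, d23) -> np.ndarray:
    """MEC radius of a point triple given its three pairwise distances.

    The MEC of three points is either the circle with the longest side as
    diameter (when the opposite angle is right/obtuse, i.e. the longest
    squared side is at least the sum of the other two squared sides —
    degenerate and collinear triples fall in this case) or the circumcircle.
    Both depend only on the side lengths, so this vectorises over arbitrary
    stacks of triples.
    """
    a = np.asarray(d12, dtype=float)
    b = np.asarray(d13, dtype=float)
    c = np.asarray(d23, dtype=float)
    a, b, c = np.broadcast_arrays(a, b, c)
    sq = np.stack([a * a, b * b, c * c])
    longest_sq = sq.max(axis=0)
    obtuse = 2.0 * longest_sq >= sq.sum(axis=0)  # longest² ≥ sum of others²
    # circumradius R = abc / sqrt((a+b+c)(−a+b+c)(a−b+c)(a+b−c))
    s = (a + b + c) * (-a + b + c) * (a - b + c) * (a + b - c)
    with np.errstate(invalid="ignore", divide="ignore"):
        circum = (a * b * c) / np.sqrt(np.maximum(s, 0.0))
    return np.where(obtuse, 0.5 * np.sqrt(longest_sq), circum)


def mec_radius(p1, p2, p3) -> float:
    """Radius (µm) of the smallest circle enclosing three points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    d12 = np.hypot(*(p1 - p2))
    d13 = np.hypot(*(p1 - p3))
    d23 = np.hypot(*(p2 - p3))
    return float(mec_radius_from_distances(d12, d13, d23))


def mec_circle(p1, p2, p3) -> tuple[tuple[float, float], float]:
    """Centre and radius of the three-point minimum enclosing circle."""
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3)]
    # diameter case: try each pair's midpoint circle
    best = None
    for i in range(3):
        for j in range(i + 1, 3):
            centre = 0.5 * (pts[i] + pts[j])
            r = 0.5 * np.hypot(*(pts[i] - pts[j]))
            k = 3 - i - j
            if np.hypot(*(pts[k] - centre)) <= r * (1 + 1e-12):
                if best is None or r < best[1]:
                    best = (centre, r)
    if best is not None:
        return (float(best[0][0]), float(best[0][1])), float(best[1])
    # acute triangle: circumcentre from perpendicular-bisector linear system
    (x1, y1), (x2, y2), (x3, y3) = pts
    A = np.array([[x2 - x1, y2 - y1], [x3 - x1, y3 - y1]])
    rhs = 0.5 * np.array(
        [x2 * x2 - x1 * x1 + y2 * y2 - y1 * y1, x3 * x3 - x1 * x1 + y3 * y3 - y1 * y1]
    )
    cx, cy = np.linalg.solve(A, rhs)
    r = float(np.hypot(x1 - cx, y1 - cy))
    return (float(cx), float(cy)), r
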
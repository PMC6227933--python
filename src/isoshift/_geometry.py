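"""Planar convex-hull helpers used in hot loops (polygon screen, metrics)."""

from __future__ import annotations

import numpy as np


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Vertices of the convex hull in counter-clockwise order.

    Andrew's monotone chain on an (m, 2) array; collinear points on the
    boundary are dropped. Degenerate inputs (all collinear) return the two
    extreme points.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return pts
    # pts sorted lexicographically by np.unique
    def half(seq):
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all collinear
        return np.array([pts[0], pts[-1]])
    return hull


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon given ordered vertices."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a point set (0 for degenerate sets)."""
    return polygon_area(convex_hull(points))


def points_in_hull(points: np.ndarray, hull: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Boolean membership of each point in a CCW convex hull (boundary in).

    For a degenerate 2-vertex hull, membership means lying within ``atol``
    of the segment.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hull = np.asarray(hull, dtype=float)
    if len(hull) == 1:
        return np.all(np.abs(pts - hull[0]) <= atol, axis=1)
    if len(hull) == 2:
        return _segment_distance(pts, hull[0], hull[1]) <= atol
    a = hull
    b = np.roll(hull, -1, axis=0)
    edge = b - a  # (E, 2)
    rel = pts[:, None, :] - a[None, :, :]  # (m, E, 2)
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    return np.all(cross >= -atol, axis=1)


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)
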
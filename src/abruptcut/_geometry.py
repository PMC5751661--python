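"""Polyline helpers shared by the contraction and texture modules.

All polylines are float arrays of shape (n, 2) in (row, col) order; closed
polylines repeat the first vertex as the last.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon


def as_closed(poly: np.ndarray) -> np.ndarray:
    """Return a copy of *poly* whose last vertex equals its first."""
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polyline must have shape (n, 2)")
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    return poly


def segment_lengths(poly: np.ndarray) -> np.ndarray:
    d = np.diff(np.asarray(poly, dtype=float), axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def polyline_length(poly: np.ndarray) -> float:
    return float(segment_lengths(poly).sum())


def densify(poly: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Insert vertices so that no segment is longer than *step* pixels."""
    poly = np.asarray(poly, dtype=float)
    out = [poly[:1]]
    for a, b in zip(poly[:-1], poly[1:]):
        seg = np.hypot(*(b - a))
        n = max(int(np.ceil(seg / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline at *n* points with even arc-length spacing.

    The returned array has shape (n, 2) and is *not* closed (the first point,
    at arc length 0, is included once).
    """
    poly = as_closed(poly)
    s = np.concatenate([[0.0], np.cumsum(segment_lengths(poly))])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    targets = np.linspace(0.0, total, n, endpoint=False)
    r = np.interp(targets, s, poly[:, 0])
    c = np.interp(targets, s, poly[:, 1])
    return np.column_stack([r, c])


def hausdorff_distance(a: np.ndarray, b: np.ndarray, step: float = 0.25) -> float:
    """Symmetric Hausdorff distance between two polylines.

    Both curves are densified to segments of at most *step* pixels so the
    vertex-to-vertex Hausdorff distance approximates the curve-to-curve one
    to within *step*.
    """
    pa = densify(np.asarray(a, float), step)
    pb = densify(np.asarray(b, float), step)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def shoelace_area(poly: np.ndarray) -> float:
    """Signed area enclosed by a closed polyline (shoelace formula)."""
    poly = as_closed(poly)
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(c[:-1] * r[1:] - c[1:] * r[:-1]))


def is_simple_closed(poly: np.ndarray) -> bool:
    """True when the closed polyline does not cross itself.

    Uses the polygon-validity predicate (a self-crossing ring is an invalid
    polygon boundary).
    """
    poly = as_closed(poly)
    if len(poly) < 4:
        return False
    coords = [(float(c), float(r)) for r, c in poly]
    return Polygon(coords).is_valid
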
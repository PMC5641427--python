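"""Shared polygon utilities for closed head contours.

A contour is an ``(V, 2)`` float array of vertices in the mathematical
(y-up) pixel frame, traversed once without repeating the closing vertex.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "as_contour",
    "signed_area",
    "perimeter",
    "centroid",
    "is_simple",
    "ensure_ccw",
]


def as_contour(points) -> np.ndarray:
    """Validate and return a contour as a float ``(V, 2)`` array.

    Raises ``ValueError`` for arrays of the wrong shape or with fewer
    than 3 vertices.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"contour must be (V, 2), got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise ValueError(f"contour needs >=3 vertices, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("contour contains non-finite coordinates")
    return arr


def signed_area(contour) -> float:
    """Shoelace signed area; positive for counter-clockwise traversal."""
    c = as_contour(contour)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(contour) -> float:
    c = as_contour(contour)
    d = np.diff(np.vstack([c, c[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def centroid(contour) -> np.ndarray:
    """Vertex-average centroid (sufficient for framing/translation)."""
    return as_contour(contour).mean(axis=0)


def is_simple(contour) -> bool:
    """True if the closed polygon does not self-intersect."""
    c = as_contour(contour)
    ring = LineString(np.vstack([c, c[:1]]))
    return bool(ring.is_simple) and Polygon(c).is_valid


def ensure_ccw(contour) -> np.ndarray:
    """Return the contour with counter-clockwise orientation.

    The first vertex is preserved so chain-code starts survive the flip.
    """
    c = as_contour(contour)
    if signed_area(c) < 0:
        c = np.vstack([c[:1], c[1:][::-1]])
    return c
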
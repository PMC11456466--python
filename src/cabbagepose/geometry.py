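"""Keypoint primitives: geometric-moment centroids, bounding rectangles and
contour extraction on binary instance masks.

The centroid is the first raw image moment ratio (m10/m00, m01/m00) over
foreground pixels with unit weight.  Bounding rectangles come in two flavours:
the axis-aligned tight box (used by the breakpoint row scan) and the
minimum-area rotated rectangle (used by the MER baseline), computed exactly by
enumerating convex-hull edge orientations — the optimal rectangle always has a
side collinear with a hull edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import EmptyMaskError

__all__ = ["BoundingRect", "centroid", "bounding_rect", "contour_points"]


@dataclass(frozen=True)
class BoundingRect:
    """Axis-aligned box, optionally with a rotated (min-area) form.

    ``rotation_deg`` is the direction of the long side (length ``w``) measured
    from the +x image axis, normalised to [0, 180); ``w >= h`` by convention.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    center: tuple[float, float] | None = None
    size: tuple[float, float] | None = None  # (w, h), w >= h
    rotation_deg: float | None = None

    @property
    def area(self) -> float:
        if self.size is not None:
            return self.size[0] * self.size[1]
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def _coords(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel centers as an (n, 2) float array of (x, y)."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise EmptyMaskError()
    return np.column_stack([xs, ys]).astype(float)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Geometric-moment centroid (m10/m00, m01/m00) of a binary mask."""
    pts = _coords(mask)
    cx, cy = pts.mean(axis=0)
    return float(cx), float(cy)


def bounding_rect(mask: np.ndarray, mode: str = "axis_aligned") -> BoundingRect:
    """Tight bounding rectangle of the foreground pixel centers.

    ``mode="axis_aligned"`` returns the min/max box; ``mode="min_area"``
    additionally carries the smallest-area rotated rectangle enclosing all
    pixel centers.
    """
    pts = _coords(mask)
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    if mode == "axis_aligned":
        return BoundingRect(float(x_min), float(y_min), float(x_max), float(y_max))
    if mode != "min_area":
        raise ValueError(f"unknown mode {mode!r}")
    center, size, rot = _min_area_rect(pts)
    return BoundingRect(
        float(x_min), float(y_min), float(x_max), float(y_max),
        center=center, size=size, rotation_deg=rot,
    )


def _min_area_rect(
    pts: np.ndarray,
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Min-area enclosing rotated rectangle of a point set.

    Enumerates hull-edge orientations (the rotated analogue of rotating
    calipers); degenerate inputs (single point, collinear points) fall back to
    a zero-width rectangle along the principal direction.
    """
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] == 1:
        x, y = uniq[0]
        return (float(x), float(y)), (0.0, 0.0), 0.0
    try:
        hull = ConvexHull(uniq)
        hp = uniq[hull.vertices]
    except QhullError:
        # collinear: rectangle degenerates to the segment along the line
        d = uniq - uniq.mean(axis=0)
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        u = vt[0]
        proj = d @ u
        length = float(proj.max() - proj.min())
        mid = uniq.mean(axis=0) + u * (proj.max() + proj.min()) / 2.0
        ang = float(np.degrees(np.arctan2(u[1], u[0]))) % 180.0
        return (float(mid[0]), float(mid[1])), (length, 0.0), ang

    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.linalg.norm(edges, axis=1)
    dirs = edges[norms > 0] / norms[norms > 0, None]
    best = None
    for ux, uy in dirs:
        u = np.array([ux, uy])
        v = np.array([-uy, ux])
        pu = hp @ u
        pv = hp @ v
        w = pu.max() - pu.min()
        h = pv.max() - pv.min()
        area = w * h
        if best is None or area < best[0] - 1e-12:
            cu = (pu.max() + pu.min()) / 2.0
            cv = (pv.max() + pv.min()) / 2.0
            c = cu * u + cv * v
            best = (area, c, w, h, u, v)
    assert best is not None
    _, c, w, h, u, v = best
    if h > w:  # long side second: swap so w >= h (ties keep the edge direction)
        w, h = h, w
        u = v
    ang = float(np.degrees(np.arctan2(u[1], u[0]))) % 180.0
    return (float(c[0]), float(c[1])), (float(w), float(h)), ang


def contour_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor, as (n, 2)
    float (x, y) coordinates; the frame border counts as background.

    Order is unspecified (set semantics); callers needing determinism should
    sort.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyMaskError()
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = m & ~interior
    ys, xs = np.nonzero(border)
    return np.column_stack([xs, ys]).astype(float)
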
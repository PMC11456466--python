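"""Baseline tilt estimators: minimum-enclosing-rectangle orientation (MER)
and skeleton-extraction line fit (SE).

Both read the tilt straight off the *visible* root mask, with no attempt to
recover the occluded junction, which is exactly why they degrade on occluded
or curved roots while the Bezier pipeline does not.

* MER: orientation of the long side of the minimum-area rotated rectangle of
  the root mask.
* SE: thin the root mask to a 1-px medial curve (Zhang–Suen thinning), then
  fit a line through the skeleton pixels by their principal direction
  (orthogonal regression — stems are near-vertical, so regressing y on x
  would be ill-conditioned).
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from . import geometry
from .errors import EmptyMaskError

__all__ = ["mer_angle", "skeletonize", "skeleton_angle", "baseline_angle"]


def _fold(rotation_deg: float, reference: str) -> float:
    """Fold a line direction in [0, 180) to an unsigned deviation in [0, 90]."""
    rot = rotation_deg % 180.0
    if reference == "vertical":
        return abs(rot - 90.0)
    if reference == "horizontal":
        return min(rot, 180.0 - rot)
    raise ValueError(f"unknown reference {reference!r}")


def mer_angle(root: np.ndarray, reference: str = "vertical") -> float:
    """Tilt of the root mask's minimum-area rectangle long side, in [0, 90].

    For square masks the long side is ambiguous; the rectangle keeps the
    first optimal hull-edge orientation found, which is deterministic for a
    fixed mask.
    """
    m = np.asarray(root, dtype=bool)
    if m.sum() < 2:
        raise EmptyMaskError("need at least 2 pixels for an orientation")
    rect = geometry.bounding_rect(m, mode="min_area")
    assert rect.rotation_deg is not None
    return _fold(rect.rotation_deg, reference)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen iterative thinning to a 1-px-wide medial curve."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyMaskError()
    return _sk_skeletonize(m, method="zhang")


def skeleton_angle(root: np.ndarray, reference: str = "vertical") -> float:
    """Tilt of the total-least-squares line through the skeleton pixels."""
    skel = skeletonize(root)
    ys, xs = np.nonzero(skel)
    pts = np.column_stack([xs, ys]).astype(float)
    if np.unique(pts, axis=0).shape[0] < 2:
        raise EmptyMaskError("skeleton collapsed to a single pixel")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    vx, vy = vt[0]
    rotation = np.degrees(np.arctan2(vy, vx))
    return _fold(float(rotation), reference)


def baseline_angle(
    root: np.ndarray, method: str, reference: str = "vertical"
) -> float:
    """Dispatch a baseline by name ('mer' or 'skeleton')."""
    if method == "mer":
        return mer_angle(root, reference)
    if method == "skeleton":
        return skeleton_angle(root, reference)
    raise ValueError(f"unknown baseline method {method!r}")
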
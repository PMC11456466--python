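"""Main-axis posture pipeline: keypoints -> breakpoint -> Bezier growth path
-> curve/head intersection -> tilt angle -> posture label.

The root–head junction of a cabbage is hidden by the outer leaves, so it
cannot be read off the segmentation masks directly.  Following the
anti-gravity stem-seeking idea — a stem grows against gravity, so the hidden
junction lies on the upward continuation of the visible root — the pipeline
interpolates a quadratic Bezier curve through three keypoints:

* P0, the geometric-moment centroid of the visible root mask;
* P1, the root contour point nearest the *breakpoint* (the midpoint of the
  topmost foreground row of the root mask, where the occluding leaves
  truncate it);
* P2, the centroid of the head mask.

The first sample of the curve that lands inside the head mask is the
predicted junction P3.  The main axis joins P2 to P3; its unsigned deviation
from the vertical (gravity) direction is the posture angle theta, compared
against a cutting threshold beta: theta <= beta is classified VERTICAL,
anything larger TILTED.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import bezier, geometry, spatial_index
from .bezier import CurveSamples
from .errors import CabbageError, EmptyMaskError, NoIntersectionError, StageError
from .scene_io import CabbageScene

__all__ = [
    "PostureLabel",
    "PostureConfig",
    "PostureResult",
    "find_break_point",
    "snap_to_contour",
    "curve_head_intersection",
    "axis_angle",
    "classify",
    "predict_posture",
]


class PostureLabel(str, enum.Enum):
    VERTICAL = "VERTICAL"
    TILTED = "TILTED"


@dataclass(frozen=True)
class PostureConfig:
    """Tunables of the posture pipeline.

    beta_deg
        Cutting threshold in degrees; the harvester tolerates axis deviations
        up to this angle.
    n_samples
        Size of the uniform t-grid used to intersect the curve with the head
        mask; 200 gives sub-pixel spacing for frames up to ~1080 px.
    angle_reference
        "vertical" measures theta as deviation from the gravity line (the
        operational reading of the posture rule); "horizontal" is the literal
        printed slope form |arctan(dy/dx)|.
    axis_top
        Which head reference point anchors the axis: the head centroid
        (default) or the midpoint of the head mask's top row.
    snap_breakpoint
        Whether to snap the raw row-midpoint breakpoint onto the nearest root
        contour point (KD-tree search) before using it as control point P1.
    """

    beta_deg: float = 10.0
    n_samples: int = 200
    angle_reference: str = "vertical"
    axis_top: str = "head_centroid"
    snap_breakpoint: bool = True

    def __post_init__(self) -> None:
        if self.beta_deg < 0:
            raise ValueError("beta_deg must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.angle_reference not in ("vertical", "horizontal"):
            raise ValueError(f"unknown angle_reference {self.angle_reference!r}")
        if self.axis_top not in ("head_centroid", "top_midpoint"):
            raise ValueError(f"unknown axis_top {self.axis_top!r}")


@dataclass
class PostureResult:
    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    axis: tuple[tuple[float, float], tuple[float, float]]
    theta_deg: float
    label: PostureLabel
    beta_deg: float
    curve: CurveSamples
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """JSON-ready summary (curve samples omitted)."""
        return {
            "p0": list(self.p0),
            "p1": list(self.p1),
            "p2": list(self.p2),
            "p3": list(self.p3),
            "theta_deg": self.theta_deg,
            "label": self.label.value,
            "beta_deg": self.beta_deg,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if k != "curve"
            },
        }


def find_break_point(root: np.ndarray) -> tuple[float, float]:
    """Midpoint of the topmost foreground row of the root mask.

    Scans rows downward from the top edge of the axis-aligned bounding
    rectangle; the first row holding root pixels is where the occluding
    leaves cut the mask, and ((x_first + x_last) / 2, y_row) is the raw
    breakpoint estimate.
    """
    m = np.asarray(root, dtype=bool)
    if not m.any():
        raise EmptyMaskError()
    row = int(np.flatnonzero(m.any(axis=1))[0])
    cols = np.flatnonzero(m[row])
    return (float(cols[0] + cols[-1]) / 2.0, float(row))


def snap_to_contour(
    candidate: tuple[float, float], root: np.ndarray
) -> tuple[float, float]:
    """Nearest root contour point to *candidate* (exact KD-tree search)."""
    pts = geometry.contour_points(root)
    tree = spatial_index.build(map(tuple, pts))
    point, _ = tree.nearest((float(candidate[0]), float(candidate[1])))
    return point


def curve_head_intersection(
    curve: CurveSamples, head: np.ndarray
) -> tuple[tuple[float, float], float]:
    """First curve sample (smallest t) whose nearest pixel lies in the head.

    Samples are mapped to pixels by round-half-up in each coordinate.  The
    curve runs from the root side (t=0) to the head centroid (t=1), so for a
    filled head the t=1 endpoint guarantees an intersection; if no sample
    lands inside, a denser grid is advised.
    """
    m = np.asarray(head, dtype=bool)
    if not m.any():
        raise EmptyMaskError()
    h, w = m.shape
    pts = curve.points
    cols = np.floor(pts[:, 0] + 0.5).astype(int)
    rows = np.floor(pts[:, 1] + 0.5).astype(int)
    valid = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    hit = np.zeros(len(pts), dtype=bool)
    hit[valid] = m[rows[valid], cols[valid]]
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise NoIntersectionError(
            "curve never enters the head mask; try a larger n_samples"
        )
    i = int(idx[0])
    x, y = pts[i]
    return (float(x), float(y)), float(curve.t_values[i])


def axis_angle(
    p_top: tuple[float, float],
    p3: tuple[float, float],
    reference: str = "vertical",
) -> float:
    """Unsigned angle of the axis through *p_top* and *p3*, in [0, 90] degrees.

    ``reference="vertical"`` measures the deviation from the gravity line
    (+y), the quantity the posture rule thresholds; ``reference="horizontal"``
    is the literal slope form |arctan((y2-y3)/(x2-x3))|.
    """
    dx = float(p_top[0]) - float(p3[0])
    dy = float(p_top[1]) - float(p3[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("axis endpoints coincide")
    if reference == "vertical":
        return math.degrees(math.atan2(abs(dx), abs(dy)))
    if reference == "horizontal":
        return math.degrees(math.atan2(abs(dy), abs(dx)))
    raise ValueError(f"unknown reference {reference!r}")


def classify(theta_deg: float, beta_deg: float) -> PostureLabel:
    """Posture rule: VERTICAL iff theta <= beta (boundary inclusive)."""
    if theta_deg < 0 or beta_deg < 0:
        raise ValueError("angles must be non-negative")
    return PostureLabel.VERTICAL if theta_deg <= beta_deg else PostureLabel.TILTED


def predict_posture(
    scene: CabbageScene,
    beta_deg: float | None = None,
    config: PostureConfig | None = None,
) -> PostureResult:
    """Run the full pipeline on a scene and return the posture estimate.

    Stage failures re-raise as :class:`StageError` with the stage name
    attached (stages: keypoints, breakpoint, curve, intersection, axis).
    """
    cfg = config or PostureConfig()
    if beta_deg is not None:
        cfg = PostureConfig(
            beta_deg=float(beta_deg),
            n_samples=cfg.n_samples,
            angle_reference=cfg.angle_reference,
            axis_top=cfg.axis_top,
            snap_breakpoint=cfg.snap_breakpoint,
        )
    diagnostics: dict[str, Any] = {"warnings": []}

    try:
        p0 = geometry.centroid(scene.root)
        p2 = geometry.centroid(scene.head)
    except CabbageError as exc:
        raise StageError("keypoints", exc) from exc
    if p0[1] <= p2[1]:
        diagnostics["warnings"].append(
            "inverted scene: root centroid not below head centroid"
        )

    try:
        raw_break = find_break_point(scene.root)
        p1 = snap_to_contour(raw_break, scene.root) if cfg.snap_breakpoint else raw_break
        diagnostics["raw_break_point"] = list(raw_break)
    except CabbageError as exc:
        raise StageError("breakpoint", exc) from exc

    try:
        curve = bezier.sample_curve([p0, p1, p2], cfg.n_samples)
    except (CabbageError, ValueError) as exc:
        raise StageError("curve", exc) from exc

    try:
        head_for_hit = np.logical_or(scene.head, np.logical_and(scene.head, scene.root))
        p3, t_hit = curve_head_intersection(curve, head_for_hit)
    except CabbageError as exc:
        raise StageError("intersection", exc) from exc
    diagnostics["intersection_t"] = t_hit
    if t_hit == 0.0:
        diagnostics["warnings"].append("degenerate start: P0 already inside head")

    if cfg.axis_top == "head_centroid":
        p_top = p2
    else:
        head_break = find_break_point(scene.head)
        p_top = head_break
        diagnostics["axis_top_point"] = list(head_break)

    try:
        theta = axis_angle(p_top, p3, cfg.angle_reference)
    except ValueError as exc:
        # coincident points: the curve entered the head at its centroid;
        # treat the axis as plumb
        diagnostics["warnings"].append(f"axis degenerate ({exc}); theta set to 0")
        theta = 0.0
    label = classify(theta, cfg.beta_deg)

    return PostureResult(
        p0=p0,
        p1=p1,
        p2=p2,
        p3=p3,
        axis=(p_top, p3),
        theta_deg=float(theta),
        label=label,
        beta_deg=cfg.beta_deg,
        curve=curve,
        diagnostics=diagnostics,
    )
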
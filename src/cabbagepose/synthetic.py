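"""Synthetic occluded-cabbage scene generator with known ground truth.

Each scene emulates what an instance segmenter hands the posture pipeline: a
head mask (filled rotated ellipse) and the *visible* part of a root mask (a
curved stem stamped as disks along a quadratic Bezier path, with the portion
nearest the head hidden by "outer leaves").  The generator records the true
main-axis angle and the true head–root junction, so angle-recovery error can
be measured exactly.

Conventions: angles are measured from the gravity (+y) direction, positive
tilting toward +x; the stem leaves the head boundary at the junction and
grows downward.  Occlusion always removes the head end of the root (that is
where the wrapping leaves sit), never the tip.  Boundary noise is
subtractive: it deletes a seeded fraction of contour pixels, emulating ragged
segmentation edges without breaking mask-containment invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from . import bezier, geometry
from .errors import CabbageError, ConfigError, GeometryError
from .scene_io import CabbageScene

__all__ = [
    "SceneParams",
    "GroundTruth",
    "PRESETS",
    "generate_scene",
    "generate_batch",
    "augment",
]

# Root-shape presets for the three field classes of cabbage root morphology:
# strongly curving roots, short stubby roots, and long straight roots.
PRESETS: dict[str, dict[str, float]] = {
    "curving": {"root_curvature": 0.6, "root_length": 40.0},
    "smallish": {"root_curvature": 0.2, "root_length": 25.0},
    "straight": {"root_curvature": 0.0, "root_length": 70.0},
}

# Fraction of root length the mid control point is offset perpendicular to the
# stem per unit curvature: curvature 1.0 bows the stem by a quarter length.
_BOW_COEFF = 0.25


@dataclass(frozen=True)
class SceneParams:
    """Geometry and nuisance parameters of one synthetic scene (pixels/degrees)."""

    frame: tuple[int, int] = (720, 1080)
    head_center: tuple[float, float] = (540.0, 300.0)
    head_axes: tuple[float, float] = (95.0, 75.0)  # (a across, b along stem)
    true_angle_deg: float = 0.0
    root_length: float = 70.0
    root_width: float = 14.0
    root_curvature: float = 0.0
    occlusion_frac: float = 0.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -60.0 <= self.true_angle_deg <= 60.0:
            raise ConfigError("true_angle_deg must lie in [-60, 60]")
        if not 0.0 <= self.occlusion_frac <= 0.8:
            raise ConfigError("occlusion_frac must lie in [0, 0.8]")
        if not 0.0 <= self.noise_frac <= 0.1:
            raise ConfigError("noise_frac must lie in [0, 0.1]")
        if not 0.0 <= self.root_curvature <= 1.0:
            raise ConfigError("root_curvature must lie in [0, 1]")
        if min(self.head_axes) <= 0 or self.root_length <= 0 or self.root_width <= 0:
            raise ConfigError("geometric parameters must be positive")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    true_angle_deg: float
    true_junction: tuple[float, float]
    root_full: np.ndarray  # pre-occlusion root mask
    preset: str | None = None


def _fill_ellipse(
    frame: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Filled ellipse with semi-axis b along the stem direction (tilted axis)."""
    h, w = frame
    a, b = axes
    A = math.radians(angle_deg)
    d = np.array([math.sin(A), math.cos(A)])  # along-stem unit vector (down)
    p = np.array([math.cos(A), -math.sin(A)])  # across-stem unit vector
    cx, cy = center
    r = max(a, b)
    x0, x1 = max(0, int(cx - r - 1)), min(w - 1, int(cx + r + 1))
    y0, y1 = max(0, int(cy - r - 1)), min(h - 1, int(cy + r + 1))
    if x1 < x0 or y1 < y0:
        raise GeometryError("head entirely outside frame")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    rx = xs - cx
    ry = ys - cy
    u = rx * p[0] + ry * p[1]
    v = rx * d[0] + ry * d[1]
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros((h, w), dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return mask


def _stamp_disks(
    frame: tuple[int, int], centers: np.ndarray, radius: float
) -> np.ndarray:
    """Union of filled disks of *radius* at each center (x, y)."""
    h, w = frame
    mask = np.zeros((h, w), dtype=bool)
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = dx**2 + dy**2 <= radius**2
    for cx, cy in centers:
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = ix - r, ix + r + 1
        y0, y1 = iy - r, iy + r + 1
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = disk.shape[1] - max(0, x1 - w)
        sy1 = disk.shape[0] - max(0, y1 - h)
        if sx1 <= sx0 or sy1 <= sy0:
            continue
        mask[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] |= disk[
            sy0:sy1, sx0:sx1
        ]
    return mask


def _drop_contour_pixels(
    mask: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Delete a random fraction of contour pixels (ragged-edge noise)."""
    if frac <= 0.0:
        return mask
    pts = geometry.contour_points(mask)
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # deterministic pixel order
    pts = pts[order]
    k = int(round(frac * len(pts)))
    if k == 0:
        return mask
    k = min(k, len(pts) - 1)  # never empty the mask
    pick = rng.choice(len(pts), size=k, replace=False)
    out = mask.copy()
    xs = pts[pick, 0].astype(int)
    ys = pts[pick, 1].astype(int)
    out[ys, xs] = False
    if not out.any():
        return mask
    return out


def generate_scene(params: SceneParams) -> tuple[CabbageScene, GroundTruth]:
    """Render one scene and its ground truth; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    h, w = params.frame
    a, b = params.head_axes
    A = math.radians(params.true_angle_deg)
    d = np.array([math.sin(A), math.cos(A)])
    perp = np.array([math.cos(A), -math.sin(A)])
    center = np.array(params.head_center, dtype=float)

    head = _fill_ellipse(params.frame, tuple(center), params.head_axes, params.true_angle_deg)
    if not head.any():
        raise GeometryError("head mask empty (outside frame?)")

    junction = center + b * d
    L = params.root_length
    bow_sign = 1.0 if rng.random() < 0.5 else -1.0
    bow = _BOW_COEFF * params.root_curvature * L * bow_sign
    ctrl = np.array(
        [junction, junction + 0.5 * L * d + bow * perp, junction + L * d]
    )
    n_pts = max(60, int(2 * L))
    samples = bezier.sample_curve(ctrl, n_pts).points
    margin = params.root_width / 2.0 + 1.0
    if (
        samples[:, 0].min() < margin
        or samples[:, 0].max() > w - 1 - margin
        or samples[:, 1].min() < margin
        or samples[:, 1].max() > h - 1 - margin
    ):
        raise GeometryError("root path leaves the frame")

    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    radius = params.root_width / 2.0
    # the root mask is NOT carved out of the head mask: real instance masks
    # overlap a little where the stem meets the head, and the posture
    # pipeline assigns overlap pixels to the head anyway
    full_root = _stamp_disks(params.frame, samples, radius)
    # outer leaves droop under gravity, so the occlusion boundary is a
    # horizontal leaf line in the image: everything above the curve point at
    # arclength occlusion_frac * root length is hidden (at zero occlusion the
    # line sits at the junction, which also trims the disk rims that would
    # otherwise wrap around the head boundary)
    ys_g = np.arange(h)[:, None]
    y_cut = float(np.interp(params.occlusion_frac * total, arclen, samples[:, 1]))
    visible_root = full_root & (ys_g >= y_cut)
    if not visible_root.any():
        raise GeometryError("occlusion removed the entire visible root")

    head_noised = _drop_contour_pixels(head, params.noise_frac, rng)
    visible_noised = _drop_contour_pixels(visible_root, params.noise_frac, rng)

    meta: dict[str, Any] = {
        "synthetic": True,
        "true_angle_deg": params.true_angle_deg,
        "true_junction_xy": [float(junction[0]), float(junction[1])],
        "params": {
            "frame": list(params.frame),
            "head_center": list(params.head_center),
            "head_axes": list(params.head_axes),
            "root_length": params.root_length,
            "root_width": params.root_width,
            "root_curvature": params.root_curvature,
            "occlusion_frac": params.occlusion_frac,
            "noise_frac": params.noise_frac,
            "seed": params.seed,
        },
    }
    scene = CabbageScene(head=head_noised, root=visible_noised, meta=meta)
    truth = GroundTruth(
        true_angle_deg=params.true_angle_deg,
        true_junction=(float(junction[0]), float(junction[1])),
        root_full=full_root,
    )
    return scene, truth


# Default sampling ranges for batches; a range may be overridden per key.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "true_angle_deg": (-40.0, 40.0),
    "occlusion_frac": (0.0, 0.4),
    "noise_frac": (0.0, 0.05),
    "root_width": (10.0, 16.0),
    "head_a": (80.0, 110.0),
    "head_b": (65.0, 90.0),
}


def _child_seed(seed: int, index: int) -> int:
    """Counter-based per-scene seed, independent of generation order."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_batch(
    n: int,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    preset: str = "mixed",
    frame: tuple[int, int] = (720, 1080),
) -> list[tuple[CabbageScene, GroundTruth]]:
    """Sample *n* scenes with per-scene parameters drawn from seeded ranges.

    ``preset`` selects one of the root-shape classes in :data:`PRESETS`, or
    "mixed" to draw a class uniformly per scene.  Per-scene seeds derive from
    the batch seed and the scene index only.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if preset != "mixed" and preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose {sorted(PRESETS)} or 'mixed'")
    ranges = dict(DEFAULT_RANGES)
    if param_ranges:
        for key, rng_pair in param_ranges.items():
            if key not in ranges:
                raise ConfigError(f"unknown parameter range {key!r}")
            lo, hi = rng_pair
            if hi < lo:
                raise ConfigError(f"empty range for {key!r}: {rng_pair}")
            ranges[key] = (float(lo), float(hi))

    out: list[tuple[CabbageScene, GroundTruth]] = []
    preset_names = sorted(PRESETS)
    h, w = frame
    for i in range(n):
        child = _child_seed(seed, i)
        rng = np.random.default_rng(child)

        def u(key: str) -> float:
            lo, hi = ranges[key]
            return float(rng.uniform(lo, hi)) if hi > lo else lo

        name = preset if preset != "mixed" else preset_names[int(rng.integers(len(preset_names)))]
        shape = PRESETS[name]
        head_axes = (u("head_a"), u("head_b"))
        # keep the whole plant inside the frame with a generous margin
        reach = head_axes[1] + shape["root_length"] * 1.3 + 20
        cx = float(rng.uniform(max(150, reach), w - max(150, reach)))
        cy = float(rng.uniform(head_axes[0] + 20, h - reach))
        params = SceneParams(
            frame=frame,
            head_center=(cx, cy),
            head_axes=head_axes,
            true_angle_deg=u("true_angle_deg"),
            root_length=shape["root_length"],
            root_width=u("root_width"),
            root_curvature=shape["root_curvature"],
            occlusion_frac=u("occlusion_frac"),
            noise_frac=u("noise_frac"),
            seed=child,
        )
        scene, truth = generate_scene(params)
        scene.meta["preset"] = name
        scene.meta["scene_index"] = i
        truth.preset = name
        out.append((scene, truth))
    return out


def _apply_mask_transform(mask: np.ndarray, op: str, arg: Any) -> np.ndarray:
    if op == "mirror":
        return np.fliplr(mask)
    if op == "flip":
        return np.flipud(mask)
    if op == "translate":
        dx, dy = arg
        return ndimage.shift(
            mask.astype(np.uint8), (dy, dx), order=0, mode="constant", cval=0
        ).astype(bool)
    raise CabbageError(f"unsupported transform {op!r}")


def augment(
    scene: CabbageScene,
    ops: Sequence[tuple],
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[CabbageScene, GroundTruth | None]:
    """Apply augmentation operators to a scene (same transform to both masks).

    Supported ops: ``("rotate", deg)``, ``("translate", (dx, dy))``,
    ``("mirror",)``, ``("flip",)``, ``("noise", frac)``, ``("occlude", frac)``.
    Brightness adjustment applies to intensity images only and is a logged
    no-op on pure masks.  Ground truth (if given) is updated for rigid
    transforms: rotation adds its angle, mirroring flips the sign; a vertical
    flip inverts the scene (flagged) but leaves the unsigned tilt unchanged.
    """
    rng = np.random.default_rng(seed)
    head = scene.head.copy()
    root = scene.root.copy()
    meta = dict(scene.meta)
    new_truth = (
        GroundTruth(
            true_angle_deg=truth.true_angle_deg,
            true_junction=truth.true_junction,
            root_full=truth.root_full.copy(),
            preset=truth.preset,
        )
        if truth is not None
        else None
    )
    h, w = head.shape
    log: list[str] = meta.setdefault("augment_log", [])  # type: ignore[assignment]

    for op_tuple in ops:
        op, *args = op_tuple
        if op in ("mirror", "flip", "translate"):
            arg = args[0] if args else None
            head = _apply_mask_transform(head, op, arg)
            root = _apply_mask_transform(root, op, arg)
            if new_truth is not None:
                jx, jy = new_truth.true_junction
                new_truth.root_full = _apply_mask_transform(new_truth.root_full, op, arg)
                if op == "mirror":
                    new_truth.true_angle_deg = -new_truth.true_angle_deg
                    new_truth.true_junction = (w - 1 - jx, jy)
                elif op == "flip":
                    new_truth.true_junction = (jx, h - 1 - jy)
                    meta["inverted"] = True
                else:
                    dx, dy = arg
                    new_truth.true_junction = (jx + dx, jy + dy)
        elif op == "rotate":
            delta = float(args[0])
            cx, cy = geometry.centroid(head)

            def rot(mask: np.ndarray) -> np.ndarray:
                return (
                    _sk_rotate(
                        mask.astype(float), delta, center=(cx, cy),
                        order=0, preserve_range=True,
                    )
                    > 0.5
                )

            head_rot = rot(head)
            if new_truth is not None:
                # rotating the *plant* does not rotate gravity: the occluding
                # outer leaves keep drooping downward, so re-apply a
                # horizontal leaf line to the rotated full root, hiding the
                # same area fraction as before
                hidden = 1.0 - root.sum() / max(1, new_truth.root_full.sum())
                full_rot = rot(new_truth.root_full)
                root = _cut_horizontal(full_rot, hidden)
                new_truth.root_full = full_rot
                new_truth.true_angle_deg += delta
                jx, jy = new_truth.true_junction
                rad = math.radians(delta)
                dxj, dyj = jx - cx, jy - cy
                # screen coordinates (y down): +delta tilts the plant toward +x
                new_truth.true_junction = (
                    cx + dxj * math.cos(rad) + dyj * math.sin(rad),
                    cy - dxj * math.sin(rad) + dyj * math.cos(rad),
                )
            else:
                root = rot(root)
            head = head_rot
        elif op == "noise":
            frac = float(args[0])
            head = _drop_contour_pixels(head, frac, rng)
            root = _drop_contour_pixels(root, frac, rng)
        elif op == "occlude":
            frac = float(args[0])
            root = _occlude_near_head(root, head, frac)
        elif op == "brightness":
            log.append("brightness is a no-op on binary masks")
        else:
            raise CabbageError(f"unknown augmentation op {op!r}")

    if not head.any() or not root.any():
        raise GeometryError("augmentation pushed a mask fully out of frame")
    out_scene = CabbageScene(head=head, root=root, meta=meta)
    return out_scene, new_truth


def _cut_horizontal(full_root: np.ndarray, hidden_frac: float) -> np.ndarray:
    """Hide roughly *hidden_frac* of the root area above a horizontal line."""
    if hidden_frac <= 0.0:
        return full_root
    row_counts = full_root.sum(axis=1)
    cum = np.cumsum(row_counts)
    target = hidden_frac * cum[-1]
    y_cut = int(np.searchsorted(cum, target))
    out = full_root.copy()
    out[:y_cut] = False
    if not out.any():
        return full_root
    return out


def _occlude_near_head(
    root: np.ndarray, head: np.ndarray, frac: float
) -> np.ndarray:
    """Remove the fraction of root pixels closest to the head region."""
    if frac <= 0.0:
        return root
    dist = ndimage.distance_transform_edt(~head)
    ys, xs = np.nonzero(root)
    k = int(round(frac * len(xs)))
    if k == 0:
        return root
    k = min(k, len(xs) - 1)
    order = np.lexsort((xs, ys, dist[ys, xs]))
    out = root.copy()
    out[ys[order[:k]], xs[order[:k]]] = False
    return out
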
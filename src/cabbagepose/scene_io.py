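"""Reading and writing masks, polygon annotations, scenes and results.

Masks are plain boolean :class:`numpy.ndarray` rasters with the usual image
convention: origin at the top-left corner, ``x`` the column index, ``y`` the
row index, gravity pointing along +y.  A :class:`CabbageScene` bundles the
head and root instance masks of one plant in a shared frame, together with a
free-form metadata record (source file, synthetic ground truth, ...).

Supported external formats are 8-bit PNG masks (0/255), Labelme-style JSON
polygon annotations and a ``meta.json`` sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import CabbageError, SchemaError

__all__ = [
    "CabbageScene",
    "read_mask_png",
    "write_mask_png",
    "polygon_to_mask",
    "read_labelme",
    "write_scene",
    "read_scene",
]

# Fraction of the smaller instance allowed to overlap the other one before a
# warning (and, ten-fold higher, an error) is raised.  Heads and roots are
# distinct organs; massive overlap means the upstream segmentation is broken.
_OVERLAP_WARN = 0.05
_OVERLAP_ERROR = 0.5


@dataclass
class CabbageScene:
    """One head mask and one root mask sharing a single image frame."""

    head: np.ndarray
    root: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=bool)
        self.root = np.asarray(self.root, dtype=bool)
        if self.head.ndim != 2 or self.root.ndim != 2:
            raise CabbageError("masks must be 2-D rasters")
        if self.head.shape != self.root.shape:
            raise CabbageError(
                f"head frame {self.head.shape} != root frame {self.root.shape}"
            )
        smaller = min(self.head.sum(), self.root.sum())
        if smaller > 0:
            overlap = np.logical_and(self.head, self.root).sum() / smaller
            if overlap > _OVERLAP_ERROR:
                raise CabbageError(
                    f"head/root overlap {overlap:.2f} exceeds {_OVERLAP_ERROR}"
                )
            if overlap > _OVERLAP_WARN:
                warnings.warn(
                    f"head/root overlap {overlap:.2f} exceeds {_OVERLAP_WARN}",
                    stacklevel=2,
                )

    @property
    def frame(self) -> tuple[int, int]:
        """(height, width) of the shared image frame."""
        return self.head.shape  # type: ignore[return-value]


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG as a boolean mask (intensity > 127 is foreground).

    RGB images are reduced with a per-pixel max over channels first, so any
    channel above the midpoint marks the pixel as foreground.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise CabbageError(f"cannot read PNG {path}: {exc}") from exc
    if arr.size == 0:
        raise CabbageError(f"zero-area image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return arr > 127


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG (deterministic bytes)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def polygon_to_mask(
    vertices: Sequence[tuple[float, float]], frame: tuple[int, int]
) -> np.ndarray:
    """Rasterize a simple polygon: a pixel is set iff its center (x, y) lies
    inside or on the polygon boundary.

    Degenerate polygons (zero area) and polygons wholly outside the frame
    yield an empty mask; downstream operations reject empty masks.
    """
    h, w = frame
    if h <= 0 or w <= 0:
        raise CabbageError("frame dimensions must be positive")
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 3:
        raise CabbageError("polygon needs at least 3 vertices")
    poly = ShapelyPolygon(verts)
    if poly.is_empty or poly.area == 0.0:
        return np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.floor(minx)))
    x1 = min(w - 1, int(np.ceil(maxx)))
    y0 = max(0, int(np.floor(miny)))
    y1 = min(h - 1, int(np.ceil(maxy)))
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    # boundary-inclusive containment of pixel centers
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(xs.shape)
    return mask


def read_labelme(
    path: str | Path, head_label: str = "head", root_label: str = "root"
) -> CabbageScene:
    """Read a Labelme JSON annotation into a :class:`CabbageScene`.

    The file must contain ``imageHeight``, ``imageWidth`` and a ``shapes``
    list with exactly one polygon per class label.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CabbageError(f"cannot read annotation {path}: {exc}") from exc
    for key in ("imageHeight", "imageWidth", "shapes"):
        if key not in data:
            raise SchemaError(f"annotation missing field {key!r}: {path}")
    frame = (int(data["imageHeight"]), int(data["imageWidth"]))
    masks: dict[str, np.ndarray] = {}
    for label in (head_label, root_label):
        shapes = [s for s in data["shapes"] if s.get("label") == label]
        if not shapes:
            raise SchemaError(f"annotation missing shape labeled {label!r}: {path}")
        if len(shapes) > 1:
            raise SchemaError(
                f"ambiguous annotation: {len(shapes)} shapes labeled {label!r}: {path}"
            )
        masks[label] = polygon_to_mask(shapes[0]["points"], frame)
    return CabbageScene(
        head=masks[head_label],
        root=masks[root_label],
        meta={"source": str(path)},
    )


def write_scene(scene: CabbageScene, out_dir: str | Path) -> list[Path]:
    """Write ``head.png``, ``root.png`` and ``meta.json`` into *out_dir*.

    Bytes are deterministic for a fixed scene, so datasets can be diffed.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CabbageError(f"cannot create directory {out}: {exc}") from exc
    h, w = scene.frame
    head_path = out / "head.png"
    root_path = out / "root.png"
    meta_path = out / "meta.json"
    write_mask_png(scene.head, head_path)
    write_mask_png(scene.root, root_path)
    meta = {"frame": [int(h), int(w)], **_jsonable(scene.meta)}
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return [head_path, root_path, meta_path]


def read_scene(scene_dir: str | Path) -> CabbageScene:
    """Read a scene previously written by :func:`write_scene`."""
    d = Path(scene_dir)
    head = read_mask_png(d / "head.png")
    root = read_mask_png(d / "root.png")
    meta: dict[str, Any] = {}
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        meta.pop("frame", None)
    return CabbageScene(head=head, root=root, meta=meta)


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays to plain JSON types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
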
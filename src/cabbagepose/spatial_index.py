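"""From-scratch 2-D KD-tree with median splitting for nearest-neighbor search.

Built as a binary tree that alternates the split dimension (x, y, x, ...) by
depth and stores the lower-median point of the current dimension at each node,
so the build recurrence is T(n) = O(n log n) and the expected query cost on
well-spread points is O(log n).  This index accelerates snapping candidate
breakpoints onto root contour points; exactness (not approximation) is part of
its contract, enforced by comparing squared distances and breaking ties
lexicographically on (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import CabbageError

__all__ = ["KDNode", "KDTree", "build", "nearest"]

Point = tuple[float, float]


@dataclass
class KDNode:
    point: Point
    split_dim: int  # 0 = x, 1 = y
    left: Optional["KDNode"] = None
    right: Optional["KDNode"] = None

    @property
    def split_value(self) -> float:
        return self.point[self.split_dim]


@dataclass
class KDTree:
    root: KDNode
    size: int
    last_visits: int = field(default=0, repr=False)  # nodes touched by the last query

    def nearest(self, query: Point) -> tuple[Point, float]:
        return nearest(self, query)


def build(points: Iterable[Point]) -> KDTree:
    """Build a KD-tree over 2-D points.

    The split dimension alternates by depth; the node point is the lower
    median in the current dimension (stable sort, so equal coordinates stay in
    input order and ties fall to the left subtree).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if not pts:
        raise CabbageError("cannot build a KD-tree over zero points")
    return KDTree(root=_build(pts, 0), size=len(pts))


def _build(pts: list[Point], depth: int) -> KDNode:
    dim = depth % 2
    pts = sorted(pts, key=lambda p: p[dim])
    m = (len(pts) - 1) // 2  # lower median
    node = KDNode(point=pts[m], split_dim=dim)
    if pts[:m]:
        node.left = _build(pts[:m], depth + 1)
    if pts[m + 1 :]:
        node.right = _build(pts[m + 1 :], depth + 1)
    return node


def nearest(tree: KDTree, query: Point) -> tuple[Point, float]:
    """Exact nearest neighbor of *query* among the indexed points.

    Ties on distance are broken by smallest (x, then y).  Internally compares
    squared distances so equal-distance candidates are ordered without
    square-root rounding; the returned distance is Euclidean.
    """
    qx, qy = float(query[0]), float(query[1])
    best_key: list = [float("inf"), float("inf"), float("inf")]  # (d2, x, y)
    visits = 0

    def visit(node: Optional[KDNode]) -> None:
        nonlocal visits
        if node is None:
            return
        visits += 1
        px, py = node.point
        d2 = (px - qx) ** 2 + (py - qy) ** 2
        key = [d2, px, py]
        if key < best_key:
            best_key[:] = key
        q = (qx, qy)
        diff = q[node.split_dim] - node.split_value
        near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
        visit(near)
        # the far half-space can still hold an equal-distance point that wins
        # the lexicographic tie, so prune only on strict inequality
        if diff * diff <= best_key[0]:
            visit(far)

    visit(tree.root)
    tree.last_visits = visits
    d2, px, py = best_key
    return (px, py), float(d2) ** 0.5
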
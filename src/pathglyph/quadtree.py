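"""QuadTree spatial index over diagram elements.

Hit-testing every element against the pointer is O(n) and scales badly on
large diagrams.  The quadtree recursively splits the canvas into four
quadrants so a point lookup descends one child per level — a handful of
quadrant-center comparisons — and only the handful of co-located elements is
actually tested, O(log n) on reasonably spread inputs.

The index holds both *points* (zero-area boxes, e.g. glyph anchors) and
*shapes* (boxes with area).  Only points count toward a leaf's capacity and
trigger splits; a shape is stored at the deepest node whose region fully
contains it, so a shape straddling a split boundary lives once in an internal
node rather than being duplicated into leaves.

Quadrants are numbered Q1..Q4 = top-left, top-right, bottom-left,
bottom-right (y grows downward).  Regions are half-open, so a point exactly
on a center axis descends deterministically into the right/bottom quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .model import BoundingBox, DiagramError, DiagramLayout

__all__ = [
    "DEFAULT_CAPACITY",
    "DEFAULT_MAX_DEPTH",
    "OutOfRegionError",
    "IndexedItem",
    "QueryStats",
    "QuadTreeNode",
    "build",
    "insert",
    "query_point",
    "query_region",
    "layout_items",
    "index_layout",
]

DEFAULT_CAPACITY = 2
DEFAULT_MAX_DEPTH = 12


class OutOfRegionError(DiagramError, ValueError):
    """An item or probe lies outside the indexed region."""


@dataclass(frozen=True)
class IndexedItem:
    """An element id with its bounding box; a point is a zero-area box."""

    id: str
    bbox: BoundingBox

    @property
    def is_point(self) -> bool:
        return self.bbox.is_point

    def hits(self, x: float, y: float) -> bool:
        if self.is_point:
            return self.bbox.x == x and self.bbox.y == y
        return self.bbox.contains_point(x, y)


@dataclass
class QueryStats:
    """Instrumentation of one lookup: how many quadrant-center comparisons
    the descent performed and how many item boxes were tested."""

    quadrant_comparisons: int = 0
    candidates_tested: int = 0


class QuadTreeNode:
    """One quadrant of the partition.

    A node is a leaf iff it has no children.  Leaves hold items directly;
    internal nodes hold only shapes too large for any child quadrant.
    """

    __slots__ = ("region", "capacity", "max_depth", "depth", "items", "children")

    def __init__(
        self,
        region: BoundingBox,
        capacity: int = DEFAULT_CAPACITY,
        max_depth: int = DEFAULT_MAX_DEPTH,
        depth: int = 0,
    ):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        if region.width <= 0 or region.height <= 0:
            raise ValueError("quadtree region must have positive area")
        self.region = region
        self.capacity = capacity
        self.max_depth = max_depth
        self.depth = depth
        self.items: list[IndexedItem] = []
        self.children: tuple["QuadTreeNode", ...] | None = None

    # -- structure ---------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def _point_count(self) -> int:
        return sum(1 for it in self.items if it.is_point)

    def _child_index(self, x: float, y: float) -> int:
        """Q1..Q4 index (0-based) for a point, half-open on the center."""
        cx, cy = self.region.center
        return (0 if x < cx else 1) + (0 if y < cy else 2)

    def _split(self) -> None:
        cx, cy = self.region.center
        x0, y0 = self.region.x, self.region.y
        w, h = self.region.width / 2.0, self.region.height / 2.0
        self.children = tuple(
            QuadTreeNode(BoundingBox(qx, qy, w, h), self.capacity, self.max_depth, self.depth + 1)
            for qx, qy in ((x0, y0), (cx, y0), (x0, cy), (cx, cy))
        )
        staying: list[IndexedItem] = []
        for it in self.items:
            target = self._route(it)
            if target is self:
                staying.append(it)
            else:
                target._insert(it)
        self.items = staying

    def _route(self, item: IndexedItem) -> "QuadTreeNode":
        """Child that should receive ``item``, or ``self`` for a shape no
        child fully contains."""
        assert self.children is not None
        if item.is_point:
            return self.children[self._child_index(item.bbox.x, item.bbox.y)]
        for child in self.children:
            if child.region.contains_box(item.bbox):
                return child
        return self

    def _insert(self, item: IndexedItem) -> None:
        node = self
        while True:
            if node.is_leaf:
                node.items.append(item)
                if (
                    item.is_point
                    and node._point_count() > node.capacity
                    and node.depth < node.max_depth
                ):
                    node._split()
                return
            target = node._route(item)
            if target is node:  # boundary-spanning shape stays here
                node.items.append(item)
                return
            node = target

    # -- iteration ---------------------------------------------------------
    def iter_nodes(self) -> Iterator["QuadTreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if node.children is not None:
                stack.extend(reversed(node.children))

    def iter_items(self) -> Iterator[IndexedItem]:
        for node in self.iter_nodes():
            yield from node.items

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_items())


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def insert(tree: QuadTreeNode, item: IndexedItem) -> None:
    """Insert one item; equivalent (up to within-leaf order) to rebuilding
    from scratch with the item appended."""
    if not item.bbox.intersects(tree.region):
        raise OutOfRegionError(f"item {item.id!r} lies outside the indexed region")
    tree._insert(item)


def build(
    items: list[IndexedItem],
    region: BoundingBox,
    capacity: int = DEFAULT_CAPACITY,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> QuadTreeNode:
    """Build a quadtree over ``items`` within ``region``."""
    root = QuadTreeNode(region, capacity=capacity, max_depth=max_depth)
    for item in items:
        insert(root, item)
    return root


def query_point(tree: QuadTreeNode, x: float, y: float) -> tuple[list[IndexedItem], QueryStats]:
    """All items under a point, plus instrumentation.

    The descent compares the point against one quadrant center per internal
    node (exactly one child is entered), testing only shapes resident on the
    path and the items of the final leaf.  Hits are ordered by id.
    """
    if not tree.region.contains_point(x, y):
        raise OutOfRegionError(f"probe ({x}, {y}) lies outside the indexed region")
    stats = QueryStats()
    hits: list[IndexedItem] = []
    node = tree
    while True:
        for item in node.items:
            stats.candidates_tested += 1
            if item.hits(x, y):
                hits.append(item)
        if node.is_leaf:
            break
        stats.quadrant_comparisons += 1
        node = node.children[node._child_index(x, y)]
    hits.sort(key=lambda it: it.id)
    return hits, stats


def query_region(tree: QuadTreeNode, rect: BoundingBox) -> list[IndexedItem]:
    """All items whose bbox intersects ``rect``, ordered by id.  Subtrees
    whose region is disjoint from ``rect`` are never descended; a disjoint
    query is an empty result, not an error."""
    hits: list[IndexedItem] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.region.intersects(rect):
            continue
        for item in node.items:
            if item.bbox.intersects(rect):
                hits.append(item)
        if node.children is not None:
            stack.extend(node.children)
    hits.sort(key=lambda it: it.id)
    return hits


# ---------------------------------------------------------------------------
# layout adapters
# ---------------------------------------------------------------------------


def layout_items(layout: DiagramLayout) -> list[IndexedItem]:
    """Indexable items of a layout: every node glyph and edge with its bbox."""
    items = [IndexedItem(g.id, g.bbox) for g in layout.nodes]
    items += [IndexedItem(e.id, e.bbox) for e in layout.edges]
    return items


def index_layout(
    layout: DiagramLayout,
    capacity: int = DEFAULT_CAPACITY,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> QuadTreeNode:
    """Build the spatial index of a layout over its canvas."""
    return build(layout_items(layout), layout.canvas, capacity=capacity, max_depth=max_depth)
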
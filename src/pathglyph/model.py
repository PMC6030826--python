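"""Diagram data model and the dual JSON file formats.

A pathway drawing is shipped as two complementary JSON files:

* the **layout** (``<pathwayId>.layout.json``) holds drawable geometry —
  positioned glyphs, reaction edges and compartments;
* the **graph** (``<pathwayId>.graph.json``) holds the full semantic content —
  every entity (including complex components and set members that have no
  glyph of their own) plus the participation of each reaction.

Both formats carry a top-level ``formatVersion`` and are described by the
JSON-Schema documents shipped under ``schemas/``.  Readers validate on load
and report the offending JSON path; writers refuse objects that violate the
invariants, so ``load(write(x)) == x`` holds for every valid object.

Coordinates are real-valued diagram units, y-down, origin at the top-left of
the canvas.  Bounding boxes are half-open, ``[x, x+width) x [y, y+height)``,
which makes hit-testing and quadrant descent deterministic.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Any, BinaryIO, Iterable, TextIO, Union

import networkx as nx

__all__ = [
    "FORMAT_VERSION",
    "RENDER_CLASSES",
    "ENTITY_TYPES",
    "CONNECTOR_ROLES",
    "DiagramError",
    "ValidationError",
    "CycleError",
    "BoundingBox",
    "Segment",
    "ReactionShape",
    "Connector",
    "Glyph",
    "ReactionEdge",
    "Compartment",
    "DiagramLayout",
    "GraphEntity",
    "GraphReaction",
    "DiagramGraph",
    "ValidationReport",
    "load_layout",
    "load_graph",
    "write_layout",
    "write_graph",
    "dumps_layout",
    "dumps_graph",
    "layout_from_dict",
    "layout_to_dict",
    "graph_from_dict",
    "graph_to_dict",
    "validate_pair",
]

FORMAT_VERSION = 1

#: Closed render-class vocabulary for layout glyphs.
RENDER_CLASSES = frozenset(
    {
        "protein",
        "chemical",
        "complex",
        "entity_set",
        "encapsulated_pathway",
        "gene",
        "rna",
        "other",
    }
)

#: Closed entity-type vocabulary for graph entities.
ENTITY_TYPES = frozenset({"protein", "chemical", "complex", "entity_set", "other"})

#: Connector roles, in their canonical serialization order.
CONNECTOR_ROLES = ("input", "output", "catalyst", "regulator")


class DiagramError(Exception):
    """Base class for every error raised by pathglyph."""


class ValidationError(DiagramError):
    """A file or object violates the format contract.

    ``path`` names the offending location (JSON-pointer-ish dotted path).
    """

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path


class CycleError(ValidationError):
    """The entity composition relation contains a cycle."""

    def __init__(self, cycle: list[str], path: str = "$.entities"):
        self.cycle = list(cycle)
        super().__init__(
            "composition cycle: " + " -> ".join(self.cycle + [self.cycle[0]]), path
        )


def _check_finite(value: float, what: str) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{what} must be finite, got {value!r}", what)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in diagram units; ``width``/``height`` may be zero.

    Containment and intersection are half-open so that tiling quadrants never
    claim a point twice.  A zero-area box behaves as a point: it "contains"
    only its own coordinate and intersects a region iff the region's half-open
    extent covers that coordinate.
    """

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "width", "height"):
            _check_finite(getattr(self, name), f"bbox.{name}")
        if self.width < 0 or self.height < 0:
            raise ValidationError(
                f"width/height must be >= 0, got {self.width} x {self.height}", "bbox"
            )

    # -- derived -----------------------------------------------------------
    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def is_point(self) -> bool:
        return self.width == 0 and self.height == 0

    # -- predicates --------------------------------------------------------
    def contains_point(self, px: float, py: float) -> bool:
        """Half-open containment; a zero-extent axis matches only exactly."""
        if self.width == 0:
            if px != self.x:
                return False
        elif not (self.x <= px < self.x2):
            return False
        if self.height == 0:
            return py == self.y
        return self.y <= py < self.y2

    @staticmethod
    def _axis_overlap(a0: float, a1: float, b0: float, b1: float) -> bool:
        if a0 == a1:  # degenerate a
            return b0 <= a0 == a0 < b1 if b0 != b1 else a0 == b0
        if b0 == b1:  # degenerate b
            return a0 <= b0 < a1
        return a0 < b1 and b0 < a1

    def intersects(self, other: "BoundingBox") -> bool:
        return self._axis_overlap(self.x, self.x2, other.x, other.x2) and self._axis_overlap(
            self.y, self.y2, other.y, other.y2
        )

    def contains_box(self, other: "BoundingBox") -> bool:
        """True iff ``other`` lies fully inside this box (closed on the far
        edge for degenerate extents, half-open otherwise)."""
        if not (self.x <= other.x and self.y <= other.y):
            return False
        x_ok = other.x2 < self.x2 or (other.width == 0 and other.x < self.x2)
        if self.width == 0:
            x_ok = other.width == 0 and other.x == self.x
        y_ok = other.y2 < self.y2 or (other.height == 0 and other.y < self.y2)
        if self.height == 0:
            y_ok = other.height == 0 and other.y == self.y
        return x_ok and y_ok

    @staticmethod
    def around_points(points: Iterable[tuple[float, float]]) -> "BoundingBox":
        pts = list(points)
        if not pts:
            raise ValueError("around_points needs at least one point")
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        return BoundingBox(min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


@dataclass(frozen=True)
class Segment:
    """One straight piece of a reaction backbone."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for name in ("x1", "y1", "x2", "y2"):
            _check_finite(getattr(self, name), f"segment.{name}")


@dataclass(frozen=True)
class ReactionShape:
    """Position and kind of the central reaction decorator."""

    x: float
    y: float
    kind: str = "transition"


@dataclass(frozen=True)
class Connector:
    """Typed endpoint attaching a reaction edge to a glyph."""

    role: str
    glyph_id: str
    stoichiometry: int = 1

    def __post_init__(self) -> None:
        if self.role not in CONNECTOR_ROLES:
            raise ValidationError(
                f"connector role must be one of {sorted(CONNECTOR_ROLES)}, got {self.role!r}",
                "connector.role",
            )
        if self.stoichiometry < 1:
            raise ValidationError("connector stoichiometry must be >= 1", "connector")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Glyph:
    """A drawn node: one shape representing an entity (possibly a whole
    nested complex or set).  ``graph_ref`` names the graph entity the glyph
    stands for; it defaults to the glyph's own id, and lets several glyph
    instances point at the same entity."""

    id: str
    render_class: str
    display_name: str
    bbox: BoundingBox
    graph_ref: str | None = None
    attachments: tuple[str, ...] = ()
    stoichiometry: int = 1

    def __post_init__(self) -> None:
        if self.render_class not in RENDER_CLASSES:
            raise ValidationError(
                f"renderClass must be one of {sorted(RENDER_CLASSES)}, got {self.render_class!r}",
                f"node[{self.id}].renderClass",
            )
        if self.stoichiometry < 1:
            raise ValidationError("stoichiometry must be >= 1", f"node[{self.id}]")

    @property
    def graph_id(self) -> str:
        return self.graph_ref if self.graph_ref is not None else self.id


@dataclass(frozen=True)
class ReactionEdge:
    """A reaction drawn as a backbone of segments with a central decorator
    and typed connectors to participant glyphs."""

    id: str
    segments: tuple[Segment, ...]
    reaction_shape: ReactionShape
    connectors: tuple[Connector, ...] = ()
    graph_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("segments must be non-empty", f"edge[{self.id}].segments")

    @property
    def graph_id(self) -> str:
        return self.graph_ref if self.graph_ref is not None else self.id

    @property
    def bbox(self) -> BoundingBox:
        pts = [(self.reaction_shape.x, self.reaction_shape.y)]
        for s in self.segments:
            pts.append((s.x1, s.y1))
            pts.append((s.x2, s.y2))
        return BoundingBox.around_points(pts)


@dataclass(frozen=True)
class Compartment:
    id: str
    display_name: str
    bbox: BoundingBox
    contained_glyph_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiagramLayout:
    """Positioned drawing of one pathway.

    ``element_count`` counts nodes and edges only; compartments are framing,
    not elements.
    """

    pathway_id: str
    canvas: BoundingBox
    compartments: tuple[Compartment, ...] = ()
    nodes: tuple[Glyph, ...] = ()
    edges: tuple[ReactionEdge, ...] = ()

    @property
    def element_count(self) -> int:
        return len(self.nodes) + len(self.edges)

    def node_by_id(self) -> dict[str, Glyph]:
        return {g.id: g for g in self.nodes}

    def edge_by_id(self) -> dict[str, ReactionEdge]:
        return {e.id: e for e in self.edges}

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        seen: set[str] = set()
        for kind, elems in (
            ("compartments", self.compartments),
            ("nodes", self.nodes),
            ("edges", self.edges),
        ):
            for i, el in enumerate(elems):
                if not el.id:
                    raise ValidationError("id must be non-empty", f"$.{kind}[{i}].id")
                if el.id in seen:
                    raise ValidationError(f"duplicate id {el.id!r}", f"$.{kind}[{i}].id")
                seen.add(el.id)
        glyph_ids = {g.id for g in self.nodes}
        for i, edge in enumerate(self.edges):
            for j, conn in enumerate(edge.connectors):
                if conn.glyph_id not in glyph_ids:
                    raise ValidationError(
                        f"connector references unknown glyph {conn.glyph_id!r}",
                        f"$.edges[{i}].connectors[{j}].glyphId",
                    )
        for i, comp in enumerate(self.compartments):
            for gid in comp.contained_glyph_ids:
                if gid not in glyph_ids:
                    raise ValidationError(
                        f"compartment contains unknown glyph {gid!r}",
                        f"$.compartments[{i}].containedGlyphIds",
                    )


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphEntity:
    """Semantic entity; ``children`` lists complex components or set members
    (empty for leaves)."""

    id: str
    entity_type: str
    display_name: str
    children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"entityType must be one of {sorted(ENTITY_TYPES)}, got {self.entity_type!r}",
                f"entity[{self.id}].entityType",
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class GraphReaction:
    id: str
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    catalysts: tuple[str, ...] = ()
    regulators: tuple[str, ...] = ()

    def participants(self) -> tuple[str, ...]:
        return self.inputs + self.outputs + self.catalysts + self.regulators


@dataclass(frozen=True)
class DiagramGraph:
    """Composition + participation network of one pathway, including entities
    with no glyph in the paired layout."""

    pathway_id: str
    entities: tuple[GraphEntity, ...] = ()
    reactions: tuple[GraphReaction, ...] = ()

    @property
    def element_count(self) -> int:
        return len(self.entities) + len(self.reactions)

    def entity_by_id(self) -> dict[str, GraphEntity]:
        return {e.id: e for e in self.entities}

    def reaction_by_id(self) -> dict[str, GraphReaction]:
        return {r.id: r for r in self.reactions}

    def validate(self) -> None:
        seen: set[str] = set()
        for kind, elems in (("entities", self.entities), ("reactions", self.reactions)):
            for i, el in enumerate(elems):
                if not el.id:
                    raise ValidationError("id must be non-empty", f"$.{kind}[{i}].id")
                if el.id in seen:
                    raise ValidationError(f"duplicate id {el.id!r}", f"$.{kind}[{i}].id")
                seen.add(el.id)
        entity_ids = {e.id for e in self.entities}
        dag = nx.DiGraph()
        dag.add_nodes_from(entity_ids)
        for i, ent in enumerate(self.entities):
            for child in ent.children:
                if child not in entity_ids:
                    raise ValidationError(
                        f"child {child!r} of {ent.id!r} does not resolve",
                        f"$.entities[{i}].children",
                    )
                dag.add_edge(ent.id, child)
        if not nx.is_directed_acyclic_graph(dag):
            cycle_edges = nx.find_cycle(dag)
            raise CycleError([a for a, _ in cycle_edges])
        for i, rxn in enumerate(self.reactions):
            for role in CONNECTOR_ROLES:
                for pid in getattr(rxn, role + "s"):
                    if pid not in entity_ids:
                        raise ValidationError(
                            f"participant {pid!r} of reaction {rxn.id!r} does not resolve",
                            f"$.reactions[{i}].{role}s",
                        )


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------

Source = Union[str, os.PathLike, TextIO, BinaryIO]


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        data = source.read()  # type: ignore[union-attr]
        return data.decode("utf-8") if isinstance(data, bytes) else data
    with open(source, "r", encoding="utf-8") as fh:
        return fh.read()


def _write_text(sink: Source, text: str) -> None:
    if hasattr(sink, "write"):
        try:
            sink.write(text)  # type: ignore[union-attr]
        except TypeError:
            sink.write(text.encode("utf-8"))  # type: ignore[union-attr]
        return
    with open(sink, "w", encoding="utf-8") as fh:
        fh.write(text)


_SENTINEL = object()


def _get(d: dict, key: str, path: str, typ: type | tuple = None, default=_SENTINEL):
    if key not in d:
        if default is not _SENTINEL:
            return default
        raise ValidationError(f"missing required field {key!r}", path)
    value = d[key]
    if typ is not None and not isinstance(value, typ):
        raise ValidationError(
            f"field {key!r} has wrong type {type(value).__name__}", f"{path}.{key}"
        )
    return value


_NUMERIC = (int, float)


def _bbox_from_dict(d: Any, path: str) -> BoundingBox:
    if not isinstance(d, dict):
        raise ValidationError("bbox must be an object", path)
    return BoundingBox(
        _get(d, "x", path, _NUMERIC),
        _get(d, "y", path, _NUMERIC),
        _get(d, "width", path, _NUMERIC),
        _get(d, "height", path, _NUMERIC),
    )


def _num(v: float) -> int | float:
    """Canonical number form: integral floats serialize as ints."""
    if isinstance(v, float) and v.is_integer():
        return int(v)
    return v


def _bbox_to_dict(b: BoundingBox) -> dict:
    return {"x": _num(b.x), "y": _num(b.y), "width": _num(b.width), "height": _num(b.height)}


def layout_from_dict(data: dict) -> DiagramLayout:
    if not isinstance(data, dict):
        raise ValidationError("layout document must be a JSON object")
    version = _get(data, "formatVersion", "$", int)
    if version != FORMAT_VERSION:
        raise ValidationError(f"unsupported formatVersion {version}", "$.formatVersion")
    compartments = []
    for i, c in enumerate(_get(data, "compartments", "$", list, default=[])):
        p = f"$.compartments[{i}]"
        compartments.append(
            Compartment(
                id=_get(c, "id", p, str),
                display_name=_get(c, "displayName", p, str, default=""),
                bbox=_bbox_from_dict(_get(c, "bbox", p), p + ".bbox"),
                contained_glyph_ids=tuple(_get(c, "containedGlyphIds", p, list, default=[])),
            )
        )
    nodes = []
    for i, n in enumerate(_get(data, "nodes", "$", list, default=[])):
        p = f"$.nodes[{i}]"
        nodes.append(
            Glyph(
                id=_get(n, "id", p, str),
                render_class=_get(n, "renderClass", p, str),
                display_name=_get(n, "displayName", p, str, default=""),
                bbox=_bbox_from_dict(_get(n, "bbox", p), p + ".bbox"),
                graph_ref=_get(n, "graphRef", p, str, default=None),
                attachments=tuple(_get(n, "attachments", p, list, default=[])),
                stoichiometry=_get(n, "stoichiometry", p, int, default=1),
            )
        )
    edges = []
    for i, e in enumerate(_get(data, "edges", "$", list, default=[])):
        p = f"$.edges[{i}]"
        segs = tuple(
            Segment(*(_get(s, k, f"{p}.segments[{j}]", _NUMERIC) for k in ("x1", "y1", "x2", "y2")))
            for j, s in enumerate(_get(e, "segments", p, list))
        )
        rs = _get(e, "reactionShape", p, dict)
        shape = ReactionShape(
            _get(rs, "x", p + ".reactionShape", _NUMERIC),
            _get(rs, "y", p + ".reactionShape", _NUMERIC),
            _get(rs, "kind", p + ".reactionShape", str, default="transition"),
        )
        conns = tuple(
            Connector(
                role=_get(c, "role", f"{p}.connectors[{j}]", str),
                glyph_id=_get(c, "glyphId", f"{p}.connectors[{j}]", str),
                stoichiometry=_get(c, "stoichiometry", f"{p}.connectors[{j}]", int, default=1),
            )
            for j, c in enumerate(_get(e, "connectors", p, list, default=[]))
        )
        edges.append(
            ReactionEdge(
                id=_get(e, "id", p, str),
                segments=segs,
                reaction_shape=shape,
                connectors=conns,
                graph_ref=_get(e, "graphRef", p, str, default=None),
            )
        )
    layout = DiagramLayout(
        pathway_id=_get(data, "pathwayId", "$", str),
        canvas=_bbox_from_dict(_get(data, "canvas", "$"), "$.canvas"),
        compartments=tuple(compartments),
        nodes=tuple(nodes),
        edges=tuple(edges),
    )
    layout.validate()
    return layout


def layout_to_dict(layout: DiagramLayout) -> dict:
    """Canonical dict form; fields holding their default value are omitted."""
    doc: dict[str, Any] = {
        "formatVersion": FORMAT_VERSION,
        "pathwayId": layout.pathway_id,
        "canvas": _bbox_to_dict(layout.canvas),
    }
    if layout.compartments:
        doc["compartments"] = [
            {
                "id": c.id,
                "displayName": c.display_name,
                "bbox": _bbox_to_dict(c.bbox),
                **({"containedGlyphIds": list(c.contained_glyph_ids)} if c.contained_glyph_ids else {}),
            }
            for c in layout.compartments
        ]
    doc["nodes"] = [
        {
            "id": g.id,
            "renderClass": g.render_class,
            "displayName": g.display_name,
            "bbox": _bbox_to_dict(g.bbox),
            **({"graphRef": g.graph_ref} if g.graph_ref is not None else {}),
            **({"attachments": list(g.attachments)} if g.attachments else {}),
            **({"stoichiometry": g.stoichiometry} if g.stoichiometry != 1 else {}),
        }
        for g in layout.nodes
    ]
    doc["edges"] = [
        {
            "id": e.id,
            "segments": [
                {"x1": _num(s.x1), "y1": _num(s.y1), "x2": _num(s.x2), "y2": _num(s.y2)}
                for s in e.segments
            ],
            "reactionShape": {
                "x": _num(e.reaction_shape.x),
                "y": _num(e.reaction_shape.y),
                **({"kind": e.reaction_shape.kind} if e.reaction_shape.kind != "transition" else {}),
            },
            **(
                {
                    "connectors": [
                        {
                            "role": c.role,
                            "glyphId": c.glyph_id,
                            **({"stoichiometry": c.stoichiometry} if c.stoichiometry != 1 else {}),
                        }
                        for c in e.connectors
                    ]
                }
                if e.connectors
                else {}
            ),
            **({"graphRef": e.graph_ref} if e.graph_ref is not None else {}),
        }
        for e in layout.edges
    ]
    return doc


def graph_from_dict(data: dict) -> DiagramGraph:
    if not isinstance(data, dict):
        raise ValidationError("graph document must be a JSON object")
    version = _get(data, "formatVersion", "$", int)
    if version != FORMAT_VERSION:
        raise ValidationError(f"unsupported formatVersion {version}", "$.formatVersion")
    entities = []
    for i, e in enumerate(_get(data, "entities", "$", list, default=[])):
        p = f"$.entities[{i}]"
        entities.append(
            GraphEntity(
                id=_get(e, "id", p, str),
                entity_type=_get(e, "entityType", p, str),
                display_name=_get(e, "displayName", p, str, default=""),
                children=tuple(_get(e, "children", p, list, default=[])),
            )
        )
    reactions = []
    for i, r in enumerate(_get(data, "reactions", "$", list, default=[])):
        p = f"$.reactions[{i}]"
        reactions.append(
            GraphReaction(
                id=_get(r, "id", p, str),
                inputs=tuple(_get(r, "inputs", p, list, default=[])),
                outputs=tuple(_get(r, "outputs", p, list, default=[])),
                catalysts=tuple(_get(r, "catalysts", p, list, default=[])),
                regulators=tuple(_get(r, "regulators", p, list, default=[])),
            )
        )
    graph = DiagramGraph(
        pathway_id=_get(data, "pathwayId", "$", str),
        entities=tuple(entities),
        reactions=tuple(reactions),
    )
    graph.validate()
    return graph


def graph_to_dict(graph: DiagramGraph) -> dict:
    return {
        "formatVersion": FORMAT_VERSION,
        "pathwayId": graph.pathway_id,
        "entities": [
            {
                "id": e.id,
                "entityType": e.entity_type,
                "displayName": e.display_name,
                **({"children": list(e.children)} if e.children else {}),
            }
            for e in graph.entities
        ],
        "reactions": [
            {
                "id": r.id,
                **({"inputs": list(r.inputs)} if r.inputs else {}),
                **({"outputs": list(r.outputs)} if r.outputs else {}),
                **({"catalysts": list(r.catalysts)} if r.catalysts else {}),
                **({"regulators": list(r.regulators)} if r.regulators else {}),
            }
            for r in graph.reactions
        ],
    }


def _loads(source: Source, what: str) -> dict:
    text = _read_text(source)
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {what}: {exc}") from exc


def load_layout(source: Source) -> DiagramLayout:
    """Read and validate a ``*.layout.json`` document."""
    return layout_from_dict(_loads(source, "layout"))


def load_graph(source: Source) -> DiagramGraph:
    """Read and validate a ``*.graph.json`` document."""
    return graph_from_dict(_loads(source, "graph"))


def dumps_layout(layout: DiagramLayout) -> str:
    """Compact canonical serialization (validates first)."""
    layout.validate()
    return json.dumps(layout_to_dict(layout), separators=(",", ":"), ensure_ascii=False)


def dumps_graph(graph: DiagramGraph) -> str:
    graph.validate()
    return json.dumps(graph_to_dict(graph), separators=(",", ":"), ensure_ascii=False)


def write_layout(layout: DiagramLayout, sink: Source) -> None:
    _write_text(sink, dumps_layout(layout))


def write_graph(graph: DiagramGraph, sink: Source) -> None:
    _write_text(sink, dumps_graph(graph))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a layout/graph pair for merge-readiness.

    ``errors`` are blocking (a drawn element with no semantic counterpart, or
    mismatching pathway ids).  ``graph_only_ids`` are expected: semantic
    elements with no glyph, e.g. the hidden components of a complex.
    """

    errors: tuple[str, ...] = ()
    graph_only_ids: tuple[str, ...] = ()
    layout_only_ids: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_pair(layout: DiagramLayout, graph: DiagramGraph) -> ValidationReport:
    """Cross-check a layout against its semantic graph.

    Every glyph and edge must resolve (via its ``graphRef``, defaulting to its
    own id) to a graph entity or reaction; graph elements without glyphs are
    reported informationally, never as errors — the graph is expected to carry
    more content than the drawing.
    """
    errors: list[str] = []
    if layout.pathway_id != graph.pathway_id:
        errors.append(
            f"pathwayId mismatch: layout={layout.pathway_id!r} graph={graph.pathway_id!r}"
        )
    entity_ids = {e.id for e in graph.entities}
    reaction_ids = {r.id for r in graph.reactions}
    referenced: set[str] = set()
    layout_only: list[str] = []
    for g in layout.nodes:
        if g.graph_id in entity_ids:
            referenced.add(g.graph_id)
        else:
            layout_only.append(g.id)
            errors.append(f"glyph {g.id!r} has no graph entity {g.graph_id!r}")
    for e in layout.edges:
        if e.graph_id in reaction_ids:
            referenced.add(e.graph_id)
        else:
            layout_only.append(e.id)
            errors.append(f"edge {e.id!r} has no graph reaction {e.graph_id!r}")
    graph_only = [i for i in list(entity_ids | reaction_ids) if i not in referenced]
    # deterministic report order: entity/reaction declaration order
    order = {el.id: i for i, el in enumerate(list(graph.entities) + list(graph.reactions))}
    graph_only.sort(key=lambda i: order[i])
    return ValidationReport(
        errors=tuple(errors),
        graph_only_ids=tuple(graph_only),
        layout_only_ids=tuple(layout_only),
    )
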
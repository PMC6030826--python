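"""Merged layout+graph context: traversal, search and halo computation.

The layout knows where things are drawn; the graph knows what they are made
of.  A :class:`DiagramContext` holds both plus the bidirectional mapping
between them, so a user action on a glyph can be propagated down into the
composition network and back up to every glyph that should light up.

The payoff is search over *invisible* content: a complex drawn as a single
glyph may hide arbitrarily nested components, and a query for one of them
must highlight the complexes that contain it even though the component
itself was never drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import (
    DiagramError,
    DiagramGraph,
    DiagramLayout,
    validate_pair,
)

__all__ = [
    "MergeError",
    "UnknownIdError",
    "DiagramContext",
    "SearchHit",
    "HaloSet",
    "merge",
    "leaf_participants",
    "containing_ancestors",
    "glyphs_for_entity",
    "search",
    "halo_set",
]


class MergeError(DiagramError):
    """The layout references semantic content the graph does not provide."""


class UnknownIdError(DiagramError, KeyError):
    """An id does not resolve in the context."""

    def __init__(self, kind: str, ident: str):
        super().__init__(f"unknown {kind} id: {ident!r}")


@dataclass(frozen=True)
class DiagramContext:
    """Merged view of one pathway.

    ``glyph_to_entity`` maps every layout node and edge id to its graph id;
    ``entity_to_glyphs`` is the exact inverse relation, and additionally
    carries an (empty) entry for every graph element with no glyph at all.
    """

    layout: DiagramLayout
    graph: DiagramGraph
    glyph_to_entity: dict[str, str]
    entity_to_glyphs: dict[str, frozenset[str]]
    parents: dict[str, frozenset[str]]  # child entity id -> direct containers

    def require_entity(self, graph_id: str):
        ent = self.graph.entity_by_id().get(graph_id)
        if ent is None:
            raise UnknownIdError("graph entity", graph_id)
        return ent


@dataclass(frozen=True)
class SearchHit:
    graph_id: str
    match_field: str  # "displayName" | "id"
    glyph_ids_to_highlight: frozenset[str]


@dataclass(frozen=True)
class HaloSet:
    """Elements to outline when an entity is selected: every reaction edge
    touching any glyph instance of the entity, plus all participants of those
    reactions (and the instances themselves)."""

    reaction_edge_ids: frozenset[str]
    participant_glyph_ids: frozenset[str]


def merge(layout: DiagramLayout, graph: DiagramGraph) -> DiagramContext:
    """Build the merged context; raises :class:`MergeError` when the pair
    does not validate cleanly."""
    report = validate_pair(layout, graph)
    if not report.ok:
        raise MergeError("; ".join(report.errors))
    g2e: dict[str, str] = {}
    e2g: dict[str, set[str]] = {e.id: set() for e in graph.entities}
    e2g.update({r.id: set() for r in graph.reactions})
    for g in layout.nodes:
        g2e[g.id] = g.graph_id
        e2g[g.graph_id].add(g.id)
    for e in layout.edges:
        g2e[e.id] = e.graph_id
        e2g[e.graph_id].add(e.id)
    parents: dict[str, set[str]] = {e.id: set() for e in graph.entities}
    for ent in graph.entities:
        for child in ent.children:
            parents[child].add(ent.id)
    return DiagramContext(
        layout=layout,
        graph=graph,
        glyph_to_entity=g2e,
        entity_to_glyphs={k: frozenset(v) for k, v in e2g.items()},
        parents={k: frozenset(v) for k, v in parents.items()},
    )


def leaf_participants(context: DiagramContext, graph_id: str) -> frozenset[str]:
    """Transitive closure over ``children``: the leaf entities ultimately
    contained in ``graph_id``.  A leaf resolves to itself; an entity reachable
    along several paths (diamond membership) appears once."""
    context.require_entity(graph_id)
    by_id = context.graph.entity_by_id()
    leaves: set[str] = set()
    seen: set[str] = set()
    stack = [graph_id]
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        ent = by_id[cur]
        if ent.is_leaf:
            leaves.add(cur)
        else:
            stack.extend(ent.children)
    return frozenset(leaves)


def containing_ancestors(context: DiagramContext, graph_id: str) -> frozenset[str]:
    """Every complex/set that (transitively) contains ``graph_id``, excluding
    the entity itself."""
    context.require_entity(graph_id)
    result: set[str] = set()
    stack = list(context.parents.get(graph_id, ()))
    while stack:
        cur = stack.pop()
        if cur in result:
            continue
        result.add(cur)
        stack.extend(context.parents.get(cur, ()))
    return frozenset(result)


def glyphs_for_entity(context: DiagramContext, graph_id: str) -> frozenset[str]:
    """Glyphs to highlight for an entity: its own instances plus the glyphs
    of every complex/set containing it.  Empty when neither the entity nor
    any container is drawn."""
    context.require_entity(graph_id)
    glyphs: set[str] = set(context.entity_to_glyphs.get(graph_id, ()))
    for anc in containing_ancestors(context, graph_id):
        glyphs |= context.entity_to_glyphs.get(anc, frozenset())
    return frozenset(glyphs)


def _hit_key(term: str, ent) -> tuple | None:
    """Ordering key for a hit, or None when the entity does not match.

    Exact matches sort first, then earliest match position, then id; the
    match is case-insensitive substring over displayName and id."""
    t = term.lower()
    name, ident = ent.display_name.lower(), ent.id.lower()
    pos_name = name.find(t)
    pos_id = ident.find(t)
    if pos_name < 0 and pos_id < 0:
        return None
    exact = 0 if (t == name or t == ident) else 1
    positions = [p for p in (pos_name, pos_id) if p >= 0]
    return (exact, min(positions), ent.id)


def search(context: DiagramContext, term: str) -> list[SearchHit]:
    """Case-insensitive substring search over *all* graph entities, visible
    or not; each hit carries the glyphs to highlight.  Ordering is
    deterministic: exact match first, then match position, then id."""
    term = term.strip()
    if not term:
        raise ValueError("search term must be non-empty")
    scored = []
    for ent in context.graph.entities:
        key = _hit_key(term, ent)
        if key is None:
            continue
        t = term.lower()
        field = "displayName" if t in ent.display_name.lower() else "id"
        scored.append(
            (
                key,
                SearchHit(
                    graph_id=ent.id,
                    match_field=field,
                    glyph_ids_to_highlight=glyphs_for_entity(context, ent.id),
                ),
            )
        )
    scored.sort(key=lambda kv: kv[0])
    return [hit for _, hit in scored]


def halo_set(context: DiagramContext, glyph_id: str) -> HaloSet:
    """Halo for a selection made on a node glyph.

    Selection is entity-level: every glyph instance of the selected entity
    participates, all reaction edges touching any instance are haloed, and so
    are all glyphs those reactions connect to.
    """
    node_ids = {g.id for g in context.layout.nodes}
    if glyph_id not in node_ids:
        raise UnknownIdError("node glyph", glyph_id)
    entity_id = context.glyph_to_entity[glyph_id]
    instances = set(context.entity_to_glyphs.get(entity_id, frozenset())) & node_ids
    edge_ids: set[str] = set()
    participants: set[str] = set(instances)
    for edge in context.layout.edges:
        touched = {c.glyph_id for c in edge.connectors}
        if touched & instances:
            edge_ids.add(edge.id)
            participants |= touched
    return HaloSet(
        reaction_edge_ids=frozenset(edge_ids),
        participant_glyph_ids=frozenset(participants),
    )
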
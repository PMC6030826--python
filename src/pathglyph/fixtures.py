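"""Worked-example fixtures and the synthetic diagram generator.

Two hand-built pathways anchor the test surface:

* the **two-reaction pathway**: R1 assembles P1 + P2 into complex C1, and R2
  associates C1 with C2 into C3, where C2 = [P3, P4, SM1, SM2] and
  C3 = [C1, C2].  The drawing shows 5 entity glyphs and 2 reaction edges
  (7 layout elements) while the semantic graph carries 9 entities and 2
  reactions (11 elements): the four constituents of C2 are never drawn.
* the **nine-element point diagram** for the spatial index: with quadrant
  capacity 2 the root splits 2/2/3/2, the overfull bottom-left quadrant
  splits twice more, and element P3 ends up alone in the innermost top-left
  quadrant.  Probing exactly at P3 therefore costs 3 quadrant comparisons
  and 1 candidate test out of the 9 elements.

The synthetic generator produces random diagrams with nested complexes/sets,
a controllable fraction of undrawn constituents, and non-overlapping glyph
placement on a jittered grid — reproducible from a seed, with a manifest of
the counts the output must exhibit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    BoundingBox,
    Compartment,
    Connector,
    DiagramGraph,
    DiagramLayout,
    Glyph,
    GraphEntity,
    GraphReaction,
    ReactionEdge,
    ReactionShape,
    Segment,
)

__all__ = [
    "FIG4_PROBE",
    "make_fig1_fixture",
    "make_fig4_fixture",
    "GeneratorParams",
    "GeneratorManifest",
    "generate_random_diagram",
    "write_fixture_files",
]


# ---------------------------------------------------------------------------
# two-reaction worked example
# ---------------------------------------------------------------------------


def _box(x: float, y: float, w: float = 60, h: float = 36) -> BoundingBox:
    return BoundingBox(x, y, w, h)


def make_fig1_fixture() -> tuple[DiagramLayout, DiagramGraph]:
    """The two-reaction pathway: 7 layout elements vs 11 graph elements."""
    entities = (
        GraphEntity("P1", "protein", "Protein 1"),
        GraphEntity("P2", "protein", "Protein 2"),
        GraphEntity("P3", "protein", "Protein 3"),
        GraphEntity("P4", "protein", "Protein 4"),
        GraphEntity("SM1", "chemical", "Small molecule 1"),
        GraphEntity("SM2", "chemical", "Small molecule 2"),
        GraphEntity("C1", "complex", "Complex 1", children=("P1", "P2")),
        GraphEntity("C2", "complex", "Complex 2", children=("P3", "P4", "SM1", "SM2")),
        GraphEntity("C3", "complex", "Complex 3", children=("C1", "C2")),
    )
    reactions = (
        GraphReaction("R1", inputs=("P1", "P2"), outputs=("C1",)),
        GraphReaction("R2", inputs=("C1", "C2"), outputs=("C3",)),
    )
    graph = DiagramGraph(pathway_id="FIG1", entities=entities, reactions=reactions)

    nodes = (
        Glyph("P1", "protein", "Protein 1", _box(20, 30)),
        Glyph("P2", "protein", "Protein 2", _box(20, 130)),
        Glyph("C1", "complex", "Complex 1", _box(170, 80)),
        Glyph("C2", "complex", "Complex 2", _box(170, 180)),
        Glyph("C3", "complex", "Complex 3", _box(330, 130)),
    )
    edges = (
        ReactionEdge(
            "R1",
            segments=(Segment(80, 48, 125, 98), Segment(80, 148, 125, 98), Segment(125, 98, 170, 98)),
            reaction_shape=ReactionShape(125, 98),
            connectors=(
                Connector("input", "P1"),
                Connector("input", "P2"),
                Connector("output", "C1"),
            ),
        ),
        ReactionEdge(
            "R2",
            segments=(
                Segment(230, 98, 280, 148),
                Segment(230, 198, 280, 148),
                Segment(280, 148, 330, 148),
            ),
            reaction_shape=ReactionShape(280, 148),
            connectors=(
                Connector("input", "C1"),
                Connector("input", "C2"),
                Connector("output", "C3"),
            ),
        ),
    )
    layout = DiagramLayout(
        pathway_id="FIG1",
        canvas=BoundingBox(0, 0, 420, 260),
        compartments=(
            Compartment(
                "cytosol",
                "cytosol",
                BoundingBox(5, 5, 410, 250),
                contained_glyph_ids=("P1", "P2", "C1", "C2", "C3"),
            ),
        ),
        nodes=nodes,
        edges=edges,
    )
    layout.validate()
    graph.validate()
    return layout, graph


# ---------------------------------------------------------------------------
# nine-element quadtree example
# ---------------------------------------------------------------------------

#: Probe placed exactly on P3; descending root -> Q3 -> Q1 -> Q1 reaches a
#: leaf holding only P3.
FIG4_PROBE = (5.0, 55.0)

_FIG4_POSITIONS = {
    # root Q1 (top-left): 2 elements
    "P1": (10.0, 10.0),
    "P2": (30.0, 20.0),
    # root Q2 (top-right): 2 elements
    "SM1": (70.0, 10.0),
    "SM2": (90.0, 30.0),
    # root Q3 (bottom-left): 3 elements -> splits; all three fall in its Q1
    # -> splits again; P3 alone in the innermost Q1
    "P3": (5.0, 55.0),
    "P4": (15.0, 65.0),
    "C1": (20.0, 70.0),
    # root Q4 (bottom-right): 2 elements
    "C2": (70.0, 70.0),
    "R1": (90.0, 90.0),
}


def make_fig4_fixture() -> tuple[DiagramLayout, tuple[float, float]]:
    """Nine point-like elements on a 100x100 canvas plus the probe point."""
    classes = {"SM1": "chemical", "SM2": "chemical", "C1": "complex", "C2": "complex", "R1": "other"}
    nodes = tuple(
        Glyph(name, classes.get(name, "protein"), name, BoundingBox(x, y, 0, 0))
        for name, (x, y) in _FIG4_POSITIONS.items()
    )
    layout = DiagramLayout(pathway_id="FIG4", canvas=BoundingBox(0, 0, 100, 100), nodes=nodes)
    layout.validate()
    return layout, FIG4_PROBE


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

_TRIVIAL_POOL = ("ATP", "ADP", "AMP", "H2O", "Pi", "NAD+", "NADH")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic diagram generator.

    Defaults emulate a mid-sized curated pathway drawing: a couple dozen
    molecules, a few nested complexes/sets, a handful of reactions, roughly a
    third of complex constituents left undrawn, and a pinch of house-keeping
    chemicals.
    """

    n_leaf_entities: int = 12
    n_complexes: int = 4
    n_sets: int = 2
    max_nesting_depth: int = 3
    n_reactions: int = 5
    n_trivial_chemicals: int = 2
    invisible_fraction: float = 0.3
    canvas_width: float = 1000.0
    canvas_height: float = 800.0

    def validate(self) -> None:
        if self.n_leaf_entities < 1:
            raise ValueError("n_leaf_entities must be >= 1")
        if self.n_trivial_chemicals > self.n_leaf_entities:
            raise ValueError("more trivial chemicals than leaf entities")
        if self.max_nesting_depth == 0 and (self.n_complexes or self.n_sets):
            raise ValueError("nesting depth 0 admits no complexes or sets")
        if self.max_nesting_depth > self.n_complexes + self.n_sets and self.max_nesting_depth > 1:
            raise ValueError("nesting depth exceeds the container budget")
        if not (0.0 <= self.invisible_fraction <= 1.0):
            raise ValueError("invisible_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorManifest:
    """Counts the generated pair is guaranteed to exhibit."""

    seed: int
    params: GeneratorParams
    expected_layout_elements: int
    expected_graph_elements: int
    expected_invisible: int


def generate_random_diagram(
    seed: int, params: GeneratorParams | None = None
) -> tuple[DiagramLayout, DiagramGraph, GeneratorManifest]:
    """Random nested diagram, reproducible from ``seed``.

    Composition is acyclic by construction (containers only adopt children
    from strictly earlier generations); an ``invisible_fraction`` share of
    the constituents gets no glyph; glyphs sit on a jittered grid and never
    overlap.
    """
    params = params or GeneratorParams()
    params.validate()
    rng = random.Random(seed)

    entities: list[GraphEntity] = []
    for i in range(params.n_leaf_entities):
        if i < params.n_trivial_chemicals:
            name = _TRIVIAL_POOL[i % len(_TRIVIAL_POOL)]
            entities.append(GraphEntity(f"L{i}", "chemical", name))
        elif rng.random() < 0.25:
            entities.append(GraphEntity(f"L{i}", "chemical", f"Metabolite {i}"))
        else:
            entities.append(GraphEntity(f"L{i}", "protein", f"Protein {i}"))

    # containers in generations: generation g may only contain generation < g
    containers: list[GraphEntity] = []
    kinds = ["complex"] * params.n_complexes + ["entity_set"] * params.n_sets
    rng.shuffle(kinds)
    generations: list[list[str]] = [[e.id for e in entities]]
    depth_budget = max(params.max_nesting_depth, 1) if kinds else 0
    for i, kind in enumerate(kinds):
        gen = 1 + (i * depth_budget) // max(len(kinds), 1) if depth_budget else 1
        gen = min(gen, len(generations))
        pool = [eid for g in generations[:gen] for eid in g]
        n_children = rng.randint(2, min(4, len(pool)))
        children = tuple(rng.sample(pool, n_children))
        ent = GraphEntity(
            f"X{i}", kind, f"{'Complex' if kind == 'complex' else 'Set'} {i}", children=children
        )
        containers.append(ent)
        if gen == len(generations):
            generations.append([])
        generations[gen].append(ent.id)
    entities += containers

    # visibility: constituents of containers may be hidden
    constituent_ids = sorted({c for ent in containers for c in ent.children})
    n_hidden = round(params.invisible_fraction * len(constituent_ids))
    hidden = set(rng.sample(constituent_ids, n_hidden)) if n_hidden else set()
    visible = [e for e in entities if e.id not in hidden]

    # reactions among visible entities
    reactions: list[GraphReaction] = []
    vis_ids = [e.id for e in visible]
    for r in range(params.n_reactions):
        n_in = rng.randint(1, min(3, len(vis_ids)))
        n_out = rng.randint(1, min(2, len(vis_ids)))
        inputs = tuple(rng.sample(vis_ids, n_in))
        outputs = tuple(rng.sample(vis_ids, n_out))
        catalysts = tuple(rng.sample(vis_ids, 1)) if rng.random() < 0.3 else ()
        reactions.append(GraphReaction(f"R{r}", inputs=inputs, outputs=outputs, catalysts=catalysts))

    graph = DiagramGraph(pathway_id=f"GEN{seed}", entities=tuple(entities), reactions=tuple(reactions))

    # glyph placement: jittered grid, one cell per visible entity
    import math

    n_vis = len(visible)
    cols = max(1, math.ceil(math.sqrt(n_vis)))
    rows = max(1, math.ceil(n_vis / cols))
    cell_w = params.canvas_width / cols
    cell_h = params.canvas_height / rows
    gw, gh = min(60.0, cell_w * 0.6), min(30.0, cell_h * 0.6)
    nodes = []
    for i, ent in enumerate(visible):
        cx = (i % cols) * cell_w
        cy = (i // cols) * cell_h
        jx = rng.uniform(0, max(cell_w - gw - 1, 0.0))
        jy = rng.uniform(0, max(cell_h - gh - 1, 0.0))
        render_class = {
            "protein": "protein",
            "chemical": "chemical",
            "complex": "complex",
            "entity_set": "entity_set",
        }.get(ent.entity_type, "other")
        nodes.append(
            Glyph(ent.id, render_class, ent.display_name, BoundingBox(cx + jx, cy + jy, gw, gh))
        )
    node_by_id = {g.id: g for g in nodes}

    edges = []
    for rxn in reactions:
        pts = []
        connectors = []
        for role, ids in (
            ("input", rxn.inputs),
            ("output", rxn.outputs),
            ("catalyst", rxn.catalysts),
        ):
            for pid in ids:
                connectors.append(Connector(role, pid))
                pts.append(node_by_id[pid].bbox.center)
        mx = sum(p[0] for p in pts) / len(pts)
        my = sum(p[1] for p in pts) / len(pts)
        segments = tuple(Segment(p[0], p[1], mx, my) for p in pts)
        edges.append(
            ReactionEdge(
                rxn.id,
                segments=segments,
                reaction_shape=ReactionShape(mx, my),
                connectors=tuple(connectors),
            )
        )

    layout = DiagramLayout(
        pathway_id=graph.pathway_id,
        canvas=BoundingBox(0, 0, params.canvas_width, params.canvas_height),
        nodes=tuple(nodes),
        edges=tuple(edges),
    )
    layout.validate()
    graph.validate()
    manifest = GeneratorManifest(
        seed=seed,
        params=params,
        expected_layout_elements=len(nodes) + len(edges),
        expected_graph_elements=graph.element_count,
        expected_invisible=len(hidden),
    )
    return layout, graph, manifest


# ---------------------------------------------------------------------------
# shipping
# ---------------------------------------------------------------------------


def write_fixture_files(directory) -> list[str]:
    """Write the worked-example fixtures as static JSON under ``directory``;
    returns the file names written."""
    import json
    import os

    from .model import write_graph, write_layout

    os.makedirs(directory, exist_ok=True)
    layout1, graph1 = make_fig1_fixture()
    layout4, probe = make_fig4_fixture()
    names = []

    def path(name: str) -> str:
        names.append(name)
        return os.path.join(directory, name)

    write_layout(layout1, path("fig1.layout.json"))
    write_graph(graph1, path("fig1.graph.json"))
    write_layout(layout4, path("fig4.layout.json"))
    with open(path("fig4.probe.json"), "w", encoding="utf-8") as fh:
        json.dump({"x": probe[0], "y": probe[1]}, fh)
    return names
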
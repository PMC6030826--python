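"""Merged context: traversal, search and halo semantics.

The traversal operations are checked against independent brute-force
recursions written directly over the ``children`` lists, never through the
context's precomputed maps.
"""

import pytest

from pathglyph.fixtures import generate_random_diagram
from pathglyph.model import (
    BoundingBox,
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
from pathglyph.overlay import (
    MergeError,
    UnknownIdError,
    containing_ancestors,
    glyphs_for_entity,
    halo_set,
    leaf_participants,
    merge,
    search,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_leaves(graph: DiagramGraph, root: str) -> set:
    by_id = {e.id: e for e in graph.entities}

    def walk(eid, seen):
        if eid in seen:
            return set()
        seen.add(eid)
        ent = by_id[eid]
        if not ent.children:
            return {eid}
        out = set()
        for child in ent.children:
            out |= walk(child, seen)
        return out

    return walk(root, set())


def brute_force_ancestors(graph: DiagramGraph, target: str) -> set:
    result = set()
    for ent in graph.entities:
        if ent.id == target:
            continue
        # reachable from ent down to target?
        stack = list(ent.children)
        by_id = {e.id: e for e in graph.entities}
        seen = set()
        while stack:
            cur = stack.pop()
            if cur == target:
                result.add(ent.id)
                break
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(by_id[cur].children)
    return result


# ---------------------------------------------------------------------------
# bespoke fixtures
# ---------------------------------------------------------------------------


def diamond_context():
    """S contains C1 and C2; both contain P (diamond membership)."""
    graph = DiagramGraph(
        pathway_id="DIA",
        entities=(
            GraphEntity("P", "protein", "Shared protein"),
            GraphEntity("C1", "complex", "c1", children=("P",)),
            GraphEntity("C2", "complex", "c2", children=("P",)),
            GraphEntity("S", "entity_set", "s", children=("C1", "C2")),
        ),
    )
    layout = DiagramLayout(
        pathway_id="DIA",
        canvas=BoundingBox(0, 0, 100, 100),
        nodes=(Glyph("S", "entity_set", "s", BoundingBox(10, 10, 20, 10)),),
    )
    return merge(layout, graph)


def two_instance_context():
    """Entity E drawn twice, each instance in a different reaction."""
    graph = DiagramGraph(
        pathway_id="TWO",
        entities=(
            GraphEntity("E", "protein", "e"),
            GraphEntity("A", "protein", "a"),
            GraphEntity("B", "protein", "b"),
        ),
        reactions=(
            GraphReaction("R1", inputs=("E",), outputs=("A",)),
            GraphReaction("R2", inputs=("E",), outputs=("B",)),
        ),
    )

    def glyph(gid, x, ref=None):
        return Glyph(gid, "protein", gid, BoundingBox(x, 10, 10, 10), graph_ref=ref)

    def edge(eid, src, dst):
        return ReactionEdge(
            eid,
            segments=(Segment(0, 0, 1, 1),),
            reaction_shape=ReactionShape(0.5, 0.5),
            connectors=(Connector("input", src), Connector("output", dst)),
        )

    layout = DiagramLayout(
        pathway_id="TWO",
        canvas=BoundingBox(0, 0, 100, 100),
        nodes=(glyph("E_a", 10, "E"), glyph("E_b", 30, "E"), glyph("A", 50), glyph("B", 70)),
        edges=(edge("R1", "E_a", "A"), edge("R2", "E_b", "B")),
    )
    return merge(layout, graph)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


class TestMerge:
    def test_invisible_constituents_have_empty_glyph_sets(self, fig1_context):
        for eid in ("P3", "P4", "SM1", "SM2"):
            assert fig1_context.entity_to_glyphs[eid] == frozenset()

    def test_maps_are_exact_inverses(self):
        for seed in range(10):
            layout, graph, _ = generate_random_diagram(seed)
            ctx = merge(layout, graph)
            for gid, eid in ctx.glyph_to_entity.items():
                assert gid in ctx.entity_to_glyphs[eid]
            for eid, glyphs in ctx.entity_to_glyphs.items():
                for gid in glyphs:
                    assert ctx.glyph_to_entity[gid] == eid

    def test_flat_identical_content_is_a_bijection(self):
        layout = DiagramLayout(
            pathway_id="X",
            canvas=BoundingBox(0, 0, 50, 50),
            nodes=(
                Glyph("A", "protein", "a", BoundingBox(1, 1, 5, 5)),
                Glyph("B", "chemical", "b", BoundingBox(10, 10, 5, 5)),
            ),
        )
        graph = DiagramGraph(
            pathway_id="X",
            entities=(GraphEntity("A", "protein", "a"), GraphEntity("B", "chemical", "b")),
        )
        ctx = merge(layout, graph)
        assert ctx.glyph_to_entity == {"A": "A", "B": "B"}
        assert all(len(v) == 1 for v in ctx.entity_to_glyphs.values())

    def test_unresolved_layout_id_is_a_merge_error(self):
        layout = DiagramLayout(
            pathway_id="X",
            canvas=BoundingBox(0, 0, 50, 50),
            nodes=(Glyph("GHOST", "protein", "g", BoundingBox(1, 1, 5, 5)),),
        )
        with pytest.raises(MergeError, match="GHOST"):
            merge(layout, DiagramGraph(pathway_id="X"))


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------


class TestLeafParticipants:
    def test_nested_complex_resolves_to_all_leaves(self, fig1_context):
        assert leaf_participants(fig1_context, "C3") == {
            "P1",
            "P2",
            "P3",
            "P4",
            "SM1",
            "SM2",
        }

    def test_leaf_resolves_to_itself(self, fig1_context):
        assert leaf_participants(fig1_context, "P1") == {"P1"}

    def test_diamond_membership_deduplicated(self):
        ctx = diamond_context()
        assert leaf_participants(ctx, "S") == {"P"}

    def test_unknown_id_raises(self, fig1_context):
        with pytest.raises(UnknownIdError):
            leaf_participants(fig1_context, "NOPE")

    def test_matches_brute_force_on_random_nested_graphs(self):
        """Oracle equivalence over 200 generated compositions."""
        checked = 0
        for seed in range(200):
            layout, graph, _ = generate_random_diagram(seed)
            ctx = merge(layout, graph)
            for ent in graph.entities:
                assert leaf_participants(ctx, ent.id) == brute_force_leaves(graph, ent.id)
                checked += 1
        assert checked > 200


class TestContainingAncestors:
    def test_buried_protein_sees_both_containers(self, fig1_context):
        assert containing_ancestors(fig1_context, "P3") == {"C2", "C3"}

    def test_top_level_entity_has_no_ancestors(self, fig1_context):
        assert containing_ancestors(fig1_context, "C3") == frozenset()

    def test_diamond_collects_all_paths(self):
        ctx = diamond_context()
        assert containing_ancestors(ctx, "P") == {"C1", "C2", "S"}

    def test_inverse_consistency_with_children_reachability(self):
        """a is an ancestor of x iff x is reachable from a via children,
        checked exhaustively on small generated graphs."""
        for seed in range(20):
            layout, graph, _ = generate_random_diagram(seed)
            ctx = merge(layout, graph)
            for ent in graph.entities:
                ancestors = containing_ancestors(ctx, ent.id)
                for other in graph.entities:
                    if other.id == ent.id:
                        continue
                    reachable = ent.id in brute_force_leaves(graph, other.id) or ent.id in {
                        e
                        for e in _descendants(graph, other.id)
                    }
                    assert (other.id in ancestors) == reachable


def _descendants(graph, root):
    by_id = {e.id: e for e in graph.entities}
    seen = set()
    stack = list(by_id[root].children)
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(by_id[cur].children)
    return seen


class TestGlyphsForEntity:
    def test_invisible_entity_highlights_its_containers(self, fig1_context):
        assert glyphs_for_entity(fig1_context, "P3") == {"C2", "C3"}

    def test_visible_top_level_entity_highlights_itself(self, fig1_context):
        assert glyphs_for_entity(fig1_context, "C3") == {"C3"}

    def test_visible_entities_always_include_their_own_glyphs(self):
        for seed in range(20):
            layout, graph, _ = generate_random_diagram(seed)
            ctx = merge(layout, graph)
            for eid, glyphs in ctx.entity_to_glyphs.items():
                if eid in {e.id for e in graph.entities} and glyphs:
                    assert glyphs <= glyphs_for_entity(ctx, eid)

    def test_entity_with_no_visible_ancestor_highlights_nothing(self):
        graph = DiagramGraph(
            pathway_id="X",
            entities=(GraphEntity("HIDDEN", "protein", "h"),),
        )
        layout = DiagramLayout(pathway_id="X", canvas=BoundingBox(0, 0, 10, 10))
        ctx = merge(layout, graph)
        assert glyphs_for_entity(ctx, "HIDDEN") == frozenset()


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


class TestSearch:
    def test_invisible_component_found_and_highlights_containers(self, fig1_context):
        hits = search(fig1_context, "P3")
        assert len(hits) == 1
        assert hits[0].graph_id == "P3"
        assert hits[0].glyph_ids_to_highlight == {"C2", "C3"}

    def test_no_match_is_empty(self, fig1_context):
        assert search(fig1_context, "XYZZY") == []

    def test_prefix_query_orders_deterministically(self, fig1_context):
        # "P" matches the proteins at position 0 and "Com_p_lex N" later;
        # ordering is match position then id, stable across calls
        hits = search(fig1_context, "P")
        ids = [h.graph_id for h in hits]
        assert ids[:4] == ["P1", "P2", "P3", "P4"]
        assert ids[4:] == ["C1", "C2", "C3"]
        assert ids == [h.graph_id for h in search(fig1_context, "P")]

    def test_exact_match_sorts_first(self, fig1_context):
        hits = search(fig1_context, "Complex 2")
        assert hits[0].graph_id == "C2"

    def test_empty_term_rejected(self, fig1_context):
        with pytest.raises(ValueError):
            search(fig1_context, "   ")

    def test_every_graph_only_entity_remains_findable(self):
        """Invisible constituents must stay reachable through search."""
        from pathglyph.model import validate_pair

        for seed in range(20):
            layout, graph, _ = generate_random_diagram(seed)
            ctx = merge(layout, graph)
            report = validate_pair(layout, graph)
            for eid in report.graph_only_ids:
                hits = search(ctx, eid)
                assert any(h.graph_id == eid for h in hits), (seed, eid)


# ---------------------------------------------------------------------------
# halo
# ---------------------------------------------------------------------------


class TestHaloSet:
    def test_selection_halo_matches_exhaustive_connector_scan(self, fig1_context):
        halo = halo_set(fig1_context, "C1")
        # oracle: scan every edge's connectors for C1
        expected_edges = {
            e.id
            for e in fig1_context.layout.edges
            if any(c.glyph_id == "C1" for c in e.connectors)
        }
        expected_participants = {"C1"}
        for e in fig1_context.layout.edges:
            if e.id in expected_edges:
                expected_participants |= {c.glyph_id for c in e.connectors}
        assert halo.reaction_edge_ids == expected_edges == {"R1", "R2"}
        assert halo.participant_glyph_ids == expected_participants

    def test_isolated_glyph_halo_is_its_own_instances(self):
        graph = DiagramGraph(
            pathway_id="X", entities=(GraphEntity("LONE", "protein", "l"),)
        )
        layout = DiagramLayout(
            pathway_id="X",
            canvas=BoundingBox(0, 0, 10, 10),
            nodes=(Glyph("LONE", "protein", "l", BoundingBox(1, 1, 2, 2)),),
        )
        halo = halo_set(merge(layout, graph), "LONE")
        assert halo.reaction_edge_ids == frozenset()
        assert halo.participant_glyph_ids == {"LONE"}

    def test_all_instances_of_selected_entity_are_covered(self):
        ctx = two_instance_context()
        halo = halo_set(ctx, "E_a")  # selecting one instance covers both
        assert halo.reaction_edge_ids == {"R1", "R2"}
        assert halo.participant_glyph_ids == {"E_a", "E_b", "A", "B"}

    def test_edge_id_is_not_a_node_glyph(self, fig1_context):
        with pytest.raises(UnknownIdError):
            halo_set(fig1_context, "R1")
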
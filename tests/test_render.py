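"""LOD renderer: zoom gating, viewport culling, layered dirty tracking and
deterministic compositing."""

import random

import pytest

from pathglyph.fixtures import make_fig1_fixture
from pathglyph.model import BoundingBox, DiagramGraph, DiagramLayout, Glyph, GraphEntity
from pathglyph.overlay import halo_set, merge
from pathglyph.quadtree import index_layout
from pathglyph.render import (
    ALL_FEATURES,
    ENTITY_LABELS,
    LAYER_ORDER,
    LODProfile,
    ROUNDED_CORNERS,
    SHOW_TRIVIAL,
    CameraState,
    InteractionState,
    RenderError,
    composite,
    features_for_zoom,
    render,
    update_interaction,
    visible_items,
)


def whole_canvas_camera(layout, zoom=1.0):
    return CameraState(
        zoom=zoom,
        pan_x=layout.canvas.x,
        pan_y=layout.canvas.y,
        viewport_width=max(1, int(layout.canvas.width * zoom + 1)),
        viewport_height=max(1, int(layout.canvas.height * zoom + 1)),
    )


def trivial_chemical_context():
    """Three house-keeping chemicals plus two proteins."""
    names = ["ATP", "ADP", "H2O", "Kinase A", "Kinase B"]
    nodes = tuple(
        Glyph(
            f"n{i}",
            "chemical" if i < 3 else "protein",
            name,
            BoundingBox(10 + 40 * i, 10, 30, 20),
        )
        for i, name in enumerate(names)
    )
    layout = DiagramLayout(pathway_id="TRIV", canvas=BoundingBox(0, 0, 300, 100), nodes=nodes)
    graph = DiagramGraph(
        pathway_id="TRIV",
        entities=tuple(
            GraphEntity(f"n{i}", "chemical" if i < 3 else "protein", name)
            for i, name in enumerate(names)
        ),
    )
    return merge(layout, graph)


class TestFeaturesForZoom:
    def test_zoomed_out_hides_trivial_molecules(self):
        feats = features_for_zoom(LODProfile(), 0.25)
        assert SHOW_TRIVIAL not in feats

    def test_maximum_threshold_enables_everything(self):
        assert features_for_zoom(LODProfile(), 2.0) == ALL_FEATURES

    def test_feature_count_monotone_over_a_zoom_sweep(self):
        profile = LODProfile()
        zooms = [0.1 + i * (8.0 - 0.1) / 49 for i in range(50)]
        counts = [len(features_for_zoom(profile, z)) for z in zooms]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_thresholds_must_increase(self):
        with pytest.raises(Exception):
            LODProfile(levels=((1.0, frozenset({ENTITY_LABELS})), (0.5, frozenset({SHOW_TRIVIAL}))))


class TestVisibleItems:
    def test_whole_viewport_sees_all_seven_elements(self, fig1_context):
        layout = fig1_context.layout
        camera = whole_canvas_camera(layout)
        index = index_layout(layout)
        ids = visible_items(fig1_context, camera, index, LODProfile())
        assert len(ids) == 7

    def test_disjoint_viewport_sees_nothing(self, fig1_context):
        layout = fig1_context.layout
        camera = CameraState(zoom=1.0, pan_x=10000, pan_y=10000)
        assert visible_items(fig1_context, camera, index_layout(layout), LODProfile()) == []

    def test_min_zoom_drops_exactly_the_trivial_chemicals(self):
        ctx = trivial_chemical_context()
        index = index_layout(ctx.layout)
        profile = LODProfile()
        full = visible_items(ctx, whole_canvas_camera(ctx.layout, 1.0), index, profile)
        coarse = visible_items(ctx, whole_canvas_camera(ctx.layout, 0.2), index, profile)
        assert len(full) - len(coarse) == 3
        assert set(coarse) == {"n3", "n4"}


class TestRender:
    def test_no_interaction_leaves_halo_and_selection_empty(self, fig1_context):
        stack = render(fig1_context, whole_canvas_camera(fig1_context.layout))
        assert stack.layers["halo"].primitives == ()
        assert stack.layers["selectionAndHighlight"].primitives == ()
        assert stack.dirty_layers() == set(LAYER_ORDER)

    def test_halo_layer_references_exactly_the_halo_set(self, fig1_context):
        stack = render(
            fig1_context,
            whole_canvas_camera(fig1_context.layout),
            interaction=InteractionState(selected_graph_id="C1"),
        )
        halo = halo_set(fig1_context, "C1")
        tags = {p.tag for p in stack.layers["halo"].primitives}
        assert tags == set(halo.reaction_edge_ids) | set(halo.participant_glyph_ids)

    def test_rendering_twice_is_byte_identical(self, fig1_context):
        camera = whole_canvas_camera(fig1_context.layout)
        interaction = InteractionState(selected_graph_id="C1", hovered_glyph_id="P1")
        a = composite(render(fig1_context, camera, interaction=interaction), "svg")
        b = composite(render(fig1_context, camera, interaction=interaction), "svg")
        assert a == b

    def test_coarse_zoom_drops_decorators_and_labels(self, fig1_context):
        coarse = render(fig1_context, whole_canvas_camera(fig1_context.layout, 0.2))
        kinds = {p.kind for p in coarse.layers["nodesAndEdges"].primitives}
        assert "decorator" not in kinds and "text" not in kinds
        assert "roundedRect" not in kinds and "rect" in kinds
        fine = render(fig1_context, whole_canvas_camera(fig1_context.layout, 2.5))
        fine_kinds = {p.kind for p in fine.layers["nodesAndEdges"].primitives}
        assert "decorator" in fine_kinds and "text" in fine_kinds
        assert "roundedRect" in fine_kinds

    def test_min_zoom_renders_no_trivial_molecule_primitive(self):
        ctx = trivial_chemical_context()
        stack = render(ctx, whole_canvas_camera(ctx.layout, 0.2))
        trivial_ids = {"n0", "n1", "n2"}
        assert all(
            p.tag not in trivial_ids for p in stack.layers["nodesAndEdges"].primitives
        )

    def test_unresolvable_interaction_is_a_render_error(self, fig1_context):
        with pytest.raises(RenderError):
            render(
                fig1_context,
                whole_canvas_camera(fig1_context.layout),
                interaction=InteractionState(hovered_glyph_id="NOPE"),
            )

    def test_element_count_monotone_in_zoom(self):
        ctx = trivial_chemical_context()
        index = index_layout(ctx.layout)
        profile = LODProfile()
        counts = [
            len(visible_items(ctx, whole_canvas_camera(ctx.layout, z), index, profile))
            for z in (0.1, 0.3, 0.6, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestUpdateInteraction:
    def setup_method(self):
        layout, graph = make_fig1_fixture()
        self.ctx = merge(layout, graph)
        self.camera = whole_canvas_camera(layout)

    def test_hover_change_dirties_only_the_top_layer(self):
        old = InteractionState()
        new = InteractionState(hovered_glyph_id="P1")
        stack = render(self.ctx, self.camera, interaction=old)
        updated = update_interaction(stack, self.ctx, self.camera, None, old, new)
        assert updated.dirty_layers() == {"selectionAndHighlight"}

    def test_selection_change_dirties_halo_and_top_layer(self):
        old = InteractionState()
        new = InteractionState(selected_graph_id="C1")
        stack = render(self.ctx, self.camera, interaction=old)
        updated = update_interaction(stack, self.ctx, self.camera, None, old, new)
        assert updated.dirty_layers() == {"halo", "selectionAndHighlight"}

    def test_no_change_dirties_nothing_and_keeps_primitives(self):
        state = InteractionState(selected_graph_id="C1")
        stack = render(self.ctx, self.camera, interaction=state)
        updated = update_interaction(stack, self.ctx, self.camera, None, state, state)
        assert updated.dirty_layers() == set()
        for name in LAYER_ORDER:
            assert updated.layers[name].primitives is stack.layers[name].primitives

    def test_untouched_layers_share_primitive_lists(self):
        old = InteractionState()
        new = InteractionState(hovered_glyph_id="P1")
        stack = render(self.ctx, self.camera, interaction=old)
        updated = update_interaction(stack, self.ctx, self.camera, None, old, new)
        assert updated.layers["nodesAndEdges"].primitives is stack.layers["nodesAndEdges"].primitives
        assert updated.layers["halo"].primitives is stack.layers["halo"].primitives

    def test_random_interaction_sequences_match_full_renders(self):
        """Incremental updates composite primitive-identically to full
        re-renders over 100 random interaction walks."""
        rng = random.Random(99)
        glyphs = [g.id for g in self.ctx.layout.nodes]
        entities = [e.id for e in self.ctx.graph.entities]
        for _ in range(100):
            state = InteractionState()
            stack = render(self.ctx, self.camera, interaction=state)
            for _ in range(5):
                new = InteractionState(
                    hovered_glyph_id=rng.choice(glyphs + [None]),
                    selected_graph_id=rng.choice(entities + [None]),
                )
                stack = update_interaction(stack, self.ctx, self.camera, None, state, new)
                state = new
            full = render(self.ctx, self.camera, interaction=state)
            assert stack.all_primitives() == full.all_primitives()
            assert composite(stack, "svg") == composite(full, "svg")


class TestComposite:
    def test_single_populated_layer_equals_its_own_primitives(self, fig1_context):
        camera = whole_canvas_camera(fig1_context.layout)
        stack = render(fig1_context, camera)
        svg = composite(stack, "svg").decode()
        for name in LAYER_ORDER:
            assert f'class="layer-{name}"' in svg

    def test_empty_stack_is_a_blank_canvas(self):
        layout = DiagramLayout(pathway_id="E", canvas=BoundingBox(0, 0, 10, 10))
        graph = DiagramGraph(pathway_id="E")
        ctx = merge(layout, graph)
        camera = CameraState(viewport_width=64, viewport_height=48)
        svg = composite(render(ctx, camera), "svg").decode()
        assert 'width="64"' in svg and 'height="48"' in svg
        assert "<rect" in svg  # only the background
        assert "data-tag" not in svg

    def test_png_output_is_deterministic_and_valid(self, fig1_context):
        camera = whole_canvas_camera(fig1_context.layout)
        stack = render(fig1_context, camera)
        png1 = composite(stack, "png")
        png2 = composite(stack, "png")
        assert png1 == png2
        assert png1[:8] == b"\x89PNG\r\n\x1a\n"

    def test_unsupported_format_rejected(self, fig1_context):
        stack = render(fig1_context, whole_canvas_camera(fig1_context.layout))
        with pytest.raises(ValueError, match="unsupported format"):
            composite(stack, "pdf")
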
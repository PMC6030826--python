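"""Multi-layer level-of-detail renderer.

The scene is rendered to a stack of four conceptual layers — compartments,
halo, nodes & edges, selection & highlight — composited in that order.  The
split exists so interaction changes touch as little as possible: moving the
pointer regenerates only the top layer, changing the selection regenerates
halo plus top layer, and everything else keeps its primitive lists untouched.

Detail is zoom-gated.  Zoomed out, house-keeping molecules (ATP, ADP, water,
...) are hidden and glyphs draw as bare rectangles over reaction backbones;
zooming in progressively adds labels, central reaction decorators, rounded
corners, node attachments and stoichiometry.  The thresholds live in a
configurable :class:`LODProfile`; feature sets are cumulative so detail never
disappears as the user zooms in.

Output is vector-first: every layer is a list of :class:`Primitive` records
tagged with their source element id (which is what the tests assert on), and
:func:`composite` serializes the stack deterministically to SVG or rasterizes
it to PNG.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import BoundingBox, DiagramError, Glyph, ValidationError
from .overlay import DiagramContext, halo_set
from .quadtree import QuadTreeNode, index_layout, query_region

__all__ = [
    "SHOW_TRIVIAL",
    "ROUNDED_CORNERS",
    "REACTION_DECORATORS",
    "NODE_ATTACHMENTS",
    "STOICHIOMETRY_LABELS",
    "ENTITY_LABELS",
    "ALL_FEATURES",
    "DEFAULT_TRIVIAL_NAMES",
    "RenderError",
    "CameraState",
    "LODProfile",
    "InteractionState",
    "Primitive",
    "Layer",
    "LayerStack",
    "LAYER_ORDER",
    "features_for_zoom",
    "visible_items",
    "render",
    "update_interaction",
    "composite",
]

SHOW_TRIVIAL = "showTrivialMolecules"
ROUNDED_CORNERS = "roundedCorners"
REACTION_DECORATORS = "reactionDecorators"
NODE_ATTACHMENTS = "nodeAttachments"
STOICHIOMETRY_LABELS = "stoichiometryLabels"
ENTITY_LABELS = "entityLabels"

ALL_FEATURES = frozenset(
    {
        SHOW_TRIVIAL,
        ROUNDED_CORNERS,
        REACTION_DECORATORS,
        NODE_ATTACHMENTS,
        STOICHIOMETRY_LABELS,
        ENTITY_LABELS,
    }
)

#: House-keeping molecules hidden in zoomed-out views (case-insensitive).
DEFAULT_TRIVIAL_NAMES = ("ADP", "ATP", "AMP", "H2O", "water", "Pi", "NAD+", "NADH")

LAYER_ORDER = ("compartments", "halo", "nodesAndEdges", "selectionAndHighlight")


class RenderError(DiagramError):
    """The render request references state that does not resolve."""


@dataclass(frozen=True)
class CameraState:
    """Viewport: zoom is the diagram-unit -> pixel scale (1.0 = native),
    (panX, panY) is the diagram-unit coordinate at the top-left pixel."""

    zoom: float = 1.0
    pan_x: float = 0.0
    pan_y: float = 0.0
    viewport_width: int = 800
    viewport_height: int = 600

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValidationError("zoom must be > 0", "camera.zoom")
        if self.viewport_width <= 0 or self.viewport_height <= 0:
            raise ValidationError("viewport dimensions must be positive", "camera")

    def viewport_world(self) -> BoundingBox:
        """The viewport expressed in diagram units."""
        return BoundingBox(
            self.pan_x,
            self.pan_y,
            self.viewport_width / self.zoom,
            self.viewport_height / self.zoom,
        )


@dataclass(frozen=True)
class LODProfile:
    """Zoom thresholds, each switching on an additional feature set.

    ``levels`` maps a minimum zoom to the features it *adds*; the active set
    at a zoom is the union over all levels at or below it, which makes the
    enabled set monotone in zoom by construction.  Below the lowest threshold
    only the minimal drawing survives.
    """

    levels: tuple[tuple[float, frozenset[str]], ...] = (
        (0.5, frozenset({ENTITY_LABELS, REACTION_DECORATORS})),
        (1.0, frozenset({ROUNDED_CORNERS, SHOW_TRIVIAL})),
        (2.0, frozenset({NODE_ATTACHMENTS, STOICHIOMETRY_LABELS})),
    )
    trivial_molecule_names: tuple[str, ...] = DEFAULT_TRIVIAL_NAMES

    def __post_init__(self) -> None:
        thresholds = [z for z, _ in self.levels]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValidationError("LOD thresholds must be strictly increasing", "lod.levels")
        unknown = set().union(*(f for _, f in self.levels or [(0, frozenset())])) - ALL_FEATURES
        if unknown:
            raise ValidationError(f"unknown features {sorted(unknown)}", "lod.levels")

    def is_trivial(self, glyph: Glyph) -> bool:
        names = {n.lower() for n in self.trivial_molecule_names}
        return glyph.render_class == "chemical" and glyph.display_name.lower() in names

    @staticmethod
    def from_dict(data: dict) -> "LODProfile":
        levels = tuple(
            (float(lv["minZoom"]), frozenset(lv["features"])) for lv in data.get("levels", [])
        )
        kwargs = {}
        if levels:
            kwargs["levels"] = levels
        if "trivialMoleculeNames" in data:
            kwargs["trivial_molecule_names"] = tuple(data["trivialMoleculeNames"])
        return LODProfile(**kwargs)


def features_for_zoom(profile: LODProfile, zoom: float) -> frozenset[str]:
    """Features active at ``zoom``: union of every level at or below it."""
    if zoom <= 0:
        raise ValueError("zoom must be > 0")
    active: set[str] = set()
    for threshold, feats in profile.levels:
        if zoom >= threshold:
            active |= feats
    return frozenset(active)


@dataclass(frozen=True)
class InteractionState:
    """Pointer state: hover is glyph-level, selection is entity-level (it
    covers every glyph instance of the selected entity)."""

    hovered_glyph_id: Optional[str] = None
    selected_graph_id: Optional[str] = None


@dataclass(frozen=True)
class Primitive:
    """One drawing command in diagram units, tagged with the element that
    produced it."""

    kind: str  # rect | roundedRect | polyline | decorator | text | attachment |
    #            stoichiometry | haloEdge | haloNode | selectionFill | hoverOutline
    tag: str
    geometry: tuple[float, ...]
    text: str = ""


@dataclass
class Layer:
    name: str
    primitives: tuple[Primitive, ...] = ()
    dirty: bool = False


@dataclass
class LayerStack:
    """The four render surfaces in compositing order, plus the camera they
    were rendered with (needed to serialize)."""

    layers: dict[str, Layer]
    camera: CameraState

    def __post_init__(self) -> None:
        if tuple(self.layers) != LAYER_ORDER:
            raise ValidationError(f"layers must be exactly {LAYER_ORDER}", "stack")

    def dirty_layers(self) -> set[str]:
        return {name for name, layer in self.layers.items() if layer.dirty}

    def clean(self) -> "LayerStack":
        """Same primitives, all dirty flags cleared (post-composite state)."""
        return LayerStack(
            layers={n: Layer(n, l.primitives, False) for n, l in self.layers.items()},
            camera=self.camera,
        )

    def all_primitives(self) -> list[Primitive]:
        out: list[Primitive] = []
        for name in LAYER_ORDER:
            out.extend(self.layers[name].primitives)
        return out


# ---------------------------------------------------------------------------
# visibility
# ---------------------------------------------------------------------------


def visible_items(
    context: DiagramContext,
    camera: CameraState,
    index: QuadTreeNode,
    profile: LODProfile,
) -> list[str]:
    """Ids of layout elements to draw: the viewport region-query of the
    spatial index, minus trivial molecules when the zoom hides them.
    Deterministically ordered by id."""
    viewport = camera.viewport_world()
    if not viewport.intersects(index.region):
        return []
    hits = query_region(index, viewport)
    feats = features_for_zoom(profile, camera.zoom)
    node_by_id = context.layout.node_by_id()
    ids = []
    for item in hits:
        glyph = node_by_id.get(item.id)
        if glyph is not None and SHOW_TRIVIAL not in feats and profile.is_trivial(glyph):
            continue
        ids.append(item.id)
    return ids


# ---------------------------------------------------------------------------
# per-layer generators (shared by render and update_interaction)
# ---------------------------------------------------------------------------


def _compartments_layer(context: DiagramContext) -> tuple[Primitive, ...]:
    prims = []
    for c in sorted(context.layout.compartments, key=lambda c: c.id):
        b = c.bbox
        prims.append(Primitive("rect", c.id, (b.x, b.y, b.width, b.height)))
        if c.display_name:
            prims.append(Primitive("text", c.id, (b.x + 4, b.y + 12), text=c.display_name))
    return tuple(prims)


def _any_instance_glyph(context: DiagramContext, graph_id: str) -> Optional[str]:
    node_ids = {g.id for g in context.layout.nodes}
    for gid in sorted(context.entity_to_glyphs.get(graph_id, frozenset())):
        if gid in node_ids:
            return gid
    return None


def _halo_layer(context: DiagramContext, interaction: InteractionState) -> tuple[Primitive, ...]:
    if interaction.selected_graph_id is None:
        return ()
    anchor = _any_instance_glyph(context, interaction.selected_graph_id)
    if anchor is None:  # selected entity has no drawn instance: nothing to halo
        return ()
    halo = halo_set(context, anchor)
    prims = []
    edge_by_id = context.layout.edge_by_id()
    node_by_id = context.layout.node_by_id()
    for eid in sorted(halo.reaction_edge_ids):
        b = edge_by_id[eid].bbox
        prims.append(Primitive("haloEdge", eid, (b.x - 3, b.y - 3, b.width + 6, b.height + 6)))
    for gid in sorted(halo.participant_glyph_ids):
        b = node_by_id[gid].bbox
        prims.append(Primitive("haloNode", gid, (b.x - 3, b.y - 3, b.width + 6, b.height + 6)))
    return tuple(prims)


def _nodes_layer(
    context: DiagramContext,
    camera: CameraState,
    profile: LODProfile,
    index: QuadTreeNode,
) -> tuple[Primitive, ...]:
    feats = features_for_zoom(profile, camera.zoom)
    node_by_id = context.layout.node_by_id()
    edge_by_id = context.layout.edge_by_id()
    prims: list[Primitive] = []
    for vid in visible_items(context, camera, index, profile):
        glyph = node_by_id.get(vid)
        if glyph is not None:
            b = glyph.bbox
            kind = "roundedRect" if ROUNDED_CORNERS in feats else "rect"
            prims.append(Primitive(kind, vid, (b.x, b.y, b.width, b.height)))
            if ENTITY_LABELS in feats and glyph.display_name:
                cx, cy = b.center
                prims.append(Primitive("text", vid, (cx, cy), text=glyph.display_name))
            if NODE_ATTACHMENTS in feats:
                for k, mark in enumerate(glyph.attachments):
                    prims.append(Primitive("attachment", vid, (b.x2, b.y + 6.0 * k), text=mark))
            if STOICHIOMETRY_LABELS in feats and glyph.stoichiometry > 1:
                prims.append(
                    Primitive("stoichiometry", vid, (b.x, b.y), text=str(glyph.stoichiometry))
                )
            continue
        edge = edge_by_id.get(vid)
        if edge is None:
            continue
        for s in edge.segments:
            prims.append(Primitive("polyline", vid, (s.x1, s.y1, s.x2, s.y2)))
        if REACTION_DECORATORS in feats:
            rs = edge.reaction_shape
            prims.append(Primitive("decorator", vid, (rs.x, rs.y), text=rs.kind))
        if STOICHIOMETRY_LABELS in feats:
            for c in edge.connectors:
                if c.stoichiometry > 1:
                    b = node_by_id[c.glyph_id].bbox
                    cx, cy = b.center
                    prims.append(
                        Primitive("stoichiometry", vid, (cx, cy - 8), text=str(c.stoichiometry))
                    )
    return tuple(prims)


def _selection_layer(
    context: DiagramContext, interaction: InteractionState
) -> tuple[Primitive, ...]:
    prims: list[Primitive] = []
    node_by_id = context.layout.node_by_id()
    edge_by_id = context.layout.edge_by_id()
    if interaction.selected_graph_id is not None:
        instances = sorted(
            gid
            for gid in context.entity_to_glyphs.get(interaction.selected_graph_id, frozenset())
            if gid in node_by_id
        )
        for gid in instances:
            b = node_by_id[gid].bbox
            prims.append(Primitive("selectionFill", gid, (b.x, b.y, b.width, b.height)))
    if interaction.hovered_glyph_id is not None:
        hid = interaction.hovered_glyph_id
        el = node_by_id.get(hid) or edge_by_id.get(hid)
        b = el.bbox
        prims.append(Primitive("hoverOutline", hid, (b.x - 1, b.y - 1, b.width + 2, b.height + 2)))
    return tuple(prims)


def _check_interaction(context: DiagramContext, interaction: InteractionState) -> None:
    if interaction.hovered_glyph_id is not None:
        if (
            interaction.hovered_glyph_id not in context.layout.node_by_id()
            and interaction.hovered_glyph_id not in context.layout.edge_by_id()
        ):
            raise RenderError(f"hovered glyph {interaction.hovered_glyph_id!r} does not resolve")
    if interaction.selected_graph_id is not None:
        if interaction.selected_graph_id not in context.entity_to_glyphs:
            raise RenderError(f"selected entity {interaction.selected_graph_id!r} does not resolve")


# ---------------------------------------------------------------------------
# render / update
# ---------------------------------------------------------------------------


def render(
    context: DiagramContext,
    camera: CameraState,
    profile: LODProfile | None = None,
    interaction: InteractionState | None = None,
    index: QuadTreeNode | None = None,
) -> LayerStack:
    """Full render of the scene into a fresh, all-dirty layer stack."""
    profile = profile or LODProfile()
    interaction = interaction or InteractionState()
    _check_interaction(context, interaction)
    if index is None:
        index = index_layout(context.layout)
    layers = {
        "compartments": Layer("compartments", _compartments_layer(context), True),
        "halo": Layer("halo", _halo_layer(context, interaction), True),
        "nodesAndEdges": Layer(
            "nodesAndEdges", _nodes_layer(context, camera, profile, index), True
        ),
        "selectionAndHighlight": Layer(
            "selectionAndHighlight", _selection_layer(context, interaction), True
        ),
    }
    return LayerStack(layers=layers, camera=camera)


def update_interaction(
    stack: LayerStack,
    context: DiagramContext,
    camera: CameraState,
    profile: LODProfile | None = None,
    old: InteractionState | None = None,
    new: InteractionState | None = None,
) -> LayerStack:
    """Minimal-redraw transition from interaction state ``old`` to ``new``.

    Only the layers affected by the change are regenerated and marked dirty:
    hover alone touches selectionAndHighlight; a selection change touches
    halo and selectionAndHighlight; nothing else is ever rebuilt.  The result
    composites identically to a full render with ``new``.
    """
    old = old or InteractionState()
    new = new or InteractionState()
    if stack.camera != camera:
        raise ValueError("stack was rendered with a different camera")
    _check_interaction(context, new)
    hover_changed = old.hovered_glyph_id != new.hovered_glyph_id
    selection_changed = old.selected_graph_id != new.selected_graph_id
    to_update: set[str] = set()
    if hover_changed or selection_changed:
        to_update.add("selectionAndHighlight")
    if selection_changed:
        to_update.add("halo")
    layers: dict[str, Layer] = {}
    for name in LAYER_ORDER:
        if name not in to_update:
            layers[name] = Layer(name, stack.layers[name].primitives, False)
        elif name == "halo":
            layers[name] = Layer(name, _halo_layer(context, new), True)
        else:
            layers[name] = Layer(name, _selection_layer(context, new), True)
    return LayerStack(layers=layers, camera=camera)


# ---------------------------------------------------------------------------
# compositing
# ---------------------------------------------------------------------------

_STYLES = {
    "rect": 'fill="#eef3fb" stroke="#274b6d" stroke-width="1"',
    "roundedRect": 'fill="#eef3fb" stroke="#274b6d" stroke-width="1" rx="6" ry="6"',
    "haloEdge": 'fill="none" stroke="#f5a623" stroke-width="4" opacity="0.6"',
    "haloNode": 'fill="none" stroke="#f5a623" stroke-width="4" opacity="0.6"',
    "selectionFill": 'fill="#1f78b4" opacity="0.35"',
    "hoverOutline": 'fill="none" stroke="#1f78b4" stroke-width="2"',
}


def _svg_escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")


def _fmt(v: float) -> str:
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return f"{v:.3f}".rstrip("0").rstrip(".")


def _primitive_svg(p: Primitive) -> str:
    tag = f' data-tag="{_svg_escape(p.tag)}"'
    if p.kind in ("rect", "roundedRect", "haloEdge", "haloNode", "selectionFill", "hoverOutline"):
        x, y, w, h = p.geometry
        extra = _STYLES[p.kind]
        return (
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" '
            f"{extra}{tag}/>"
        )
    if p.kind == "polyline":
        x1, y1, x2, y2 = p.geometry
        return (
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="#333333" stroke-width="1"{tag}/>'
        )
    if p.kind == "decorator":
        x, y = p.geometry
        return f'<rect x="{_fmt(x - 4)}" y="{_fmt(y - 4)}" width="8" height="8" fill="#ffffff" stroke="#333333" stroke-width="1"{tag}/>'
    if p.kind in ("text", "stoichiometry", "attachment"):
        x, y = p.geometry
        size = 10 if p.kind == "text" else 7
        return (
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{size}" font-family="sans-serif" '
            f'text-anchor="middle" fill="#111111"{tag}>{_svg_escape(p.text)}</text>'
        )
    raise RenderError(f"unknown primitive kind {p.kind!r}")


def _to_svg(stack: LayerStack) -> bytes:
    cam = stack.camera
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{cam.viewport_width}" height="{cam.viewport_height}" '
        f'viewBox="0 0 {cam.viewport_width} {cam.viewport_height}">',
        '<rect x="0" y="0" width="100%" height="100%" fill="#ffffff"/>',
        f'<g transform="scale({_fmt(cam.zoom)}) translate({_fmt(-cam.pan_x)},{_fmt(-cam.pan_y)})">',
    ]
    for name in LAYER_ORDER:
        lines.append(f'<g class="layer-{name}">')
        lines.extend(_primitive_svg(p) for p in stack.layers[name].primitives)
        lines.append("</g>")
    lines.append("</g>")
    lines.append("</svg>")
    return ("\n".join(lines) + "\n").encode("utf-8")


def _to_png(stack: LayerStack) -> bytes:
    from PIL import Image, ImageDraw

    cam = stack.camera
    img = Image.new("RGB", (cam.viewport_width, cam.viewport_height), "#ffffff")
    draw = ImageDraw.Draw(img)

    def tx(x: float, y: float) -> tuple[float, float]:
        return ((x - cam.pan_x) * cam.zoom, (y - cam.pan_y) * cam.zoom)

    for name in LAYER_ORDER:
        for p in stack.layers[name].primitives:
            if p.kind in (
                "rect",
                "roundedRect",
                "haloEdge",
                "haloNode",
                "selectionFill",
                "hoverOutline",
            ):
                x, y, w, h = p.geometry
                x0, y0 = tx(x, y)
                x1, y1 = tx(x + w, y + h)
                fill = "#dce8f7" if p.kind in ("rect", "roundedRect") else None
                outline = {"selectionFill": "#1f78b4"}.get(p.kind, "#555555")
                if x1 > x0 and y1 > y0:
                    draw.rectangle((x0, y0, x1, y1), fill=fill, outline=outline)
            elif p.kind == "polyline":
                x1_, y1_, x2_, y2_ = p.geometry
                draw.line([tx(x1_, y1_), tx(x2_, y2_)], fill="#333333")
            elif p.kind == "decorator":
                x, y = tx(*p.geometry)
                draw.rectangle((x - 3, y - 3, x + 3, y + 3), outline="#333333")
            elif p.kind in ("text", "stoichiometry", "attachment"):
                draw.text(tx(*p.geometry), p.text, fill="#111111")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def composite(stack: LayerStack, format: str = "svg") -> bytes:
    """Flatten the stack, layers in order, to image bytes.  Deterministic for
    identical stacks."""
    if format == "svg":
        return _to_svg(stack)
    if format == "png":
        return _to_png(stack)
    raise ValueError(f"unsupported format {format!r} (expected 'svg' or 'png')")
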
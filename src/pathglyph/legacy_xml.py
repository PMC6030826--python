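"""Legacy XML dialect and the XML -> JSON converter.

Earlier viewer generations shipped diagram layouts as XML.  This module
defines a small element-per-glyph, attribute-per-field dialect covering the
layout content, plus a converter to the current JSON format.  Every field is
written explicitly (legacy serializers did not omit defaults), which is also
what makes the format comparison honest: for any diagram with at least one
element, the compact JSON serialization is strictly smaller than this XML.

The dialect:

.. code-block:: xml

    <?xml version="1.0" encoding="UTF-8"?>
    <diagram pathwayId="PW1" formatVersion="1">
      <canvas x="0" y="0" width="400" height="200"/>
      <compartment id="cyto" displayName="cytosol" x=".." y=".." width=".." height="..">
        <contains ref="C1"/>
      </compartment>
      <node id="C1" graphRef="C1" renderClass="complex" displayName="C1"
            x=".." y=".." width=".." height=".." stoichiometry="1">
        <attachment mark="P"/>
      </node>
      <edge id="R1" graphRef="R1">
        <segment x1=".." y1=".." x2=".." y2=".."/>
        <reactionShape x=".." y=".." kind="transition"/>
        <connector role="input" glyphId="P1" stoichiometry="1"/>
      </edge>
    </diagram>
"""

from __future__ import annotations

from typing import Union

from lxml import etree

from .model import (
    BoundingBox,
    Compartment,
    Connector,
    DiagramLayout,
    FORMAT_VERSION,
    Glyph,
    ReactionEdge,
    ReactionShape,
    Segment,
    ValidationError,
    dumps_layout,
)

__all__ = ["layout_to_legacy_xml", "parse_legacy_xml", "convert_legacy_xml"]

_XML_DECL = '<?xml version="1.0" encoding="UTF-8"?>\n'


def _fmt(v: float) -> str:
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(v)


def _bbox_attrs(el: etree._Element, b: BoundingBox) -> None:
    el.set("x", _fmt(b.x))
    el.set("y", _fmt(b.y))
    el.set("width", _fmt(b.width))
    el.set("height", _fmt(b.height))


def layout_to_legacy_xml(layout: DiagramLayout) -> bytes:
    """Serialize a layout in the legacy dialect (used to build comparison and
    converter-test inputs; the modern pipeline never writes XML)."""
    layout.validate()
    root = etree.Element("diagram")
    root.set("pathwayId", layout.pathway_id)
    root.set("formatVersion", str(FORMAT_VERSION))
    canvas = etree.SubElement(root, "canvas")
    _bbox_attrs(canvas, layout.canvas)
    for c in layout.compartments:
        el = etree.SubElement(root, "compartment")
        el.set("id", c.id)
        el.set("displayName", c.display_name)
        _bbox_attrs(el, c.bbox)
        for ref in c.contained_glyph_ids:
            etree.SubElement(el, "contains").set("ref", ref)
    for g in layout.nodes:
        el = etree.SubElement(root, "node")
        el.set("id", g.id)
        el.set("graphRef", g.graph_id)
        el.set("renderClass", g.render_class)
        el.set("displayName", g.display_name)
        _bbox_attrs(el, g.bbox)
        el.set("stoichiometry", str(g.stoichiometry))
        for mark in g.attachments:
            etree.SubElement(el, "attachment").set("mark", mark)
    for e in layout.edges:
        el = etree.SubElement(root, "edge")
        el.set("id", e.id)
        el.set("graphRef", e.graph_id)
        for s in e.segments:
            seg = etree.SubElement(el, "segment")
            seg.set("x1", _fmt(s.x1))
            seg.set("y1", _fmt(s.y1))
            seg.set("x2", _fmt(s.x2))
            seg.set("y2", _fmt(s.y2))
        shape = etree.SubElement(el, "reactionShape")
        shape.set("x", _fmt(e.reaction_shape.x))
        shape.set("y", _fmt(e.reaction_shape.y))
        shape.set("kind", e.reaction_shape.kind)
        for c in e.connectors:
            conn = etree.SubElement(el, "connector")
            conn.set("role", c.role)
            conn.set("glyphId", c.glyph_id)
            conn.set("stoichiometry", str(c.stoichiometry))
    body = etree.tostring(root, encoding="unicode")
    return (_XML_DECL + body + "\n").encode("utf-8")


def _float_attr(el: etree._Element, name: str, path: str) -> float:
    raw = el.get(name)
    if raw is None:
        raise ValidationError(f"missing attribute {name!r}", path)
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(f"attribute {name!r} is not numeric: {raw!r}", path) from exc


def _bbox_of(el: etree._Element, path: str) -> BoundingBox:
    return BoundingBox(*(_float_attr(el, k, path) for k in ("x", "y", "width", "height")))


def parse_legacy_xml(source: Union[str, bytes, "os.PathLike"]) -> DiagramLayout:
    """Parse the legacy dialect into a validated :class:`DiagramLayout`."""
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed XML: {exc}") from exc
    if root.tag != "diagram":
        raise ValidationError(f"root element must be <diagram>, got <{root.tag}>")
    canvas_el = root.find("canvas")
    if canvas_el is None:
        raise ValidationError("missing <canvas>")
    compartments, nodes, edges = [], [], []
    for el in root:
        if el.tag == "compartment":
            compartments.append(
                Compartment(
                    id=el.get("id", ""),
                    display_name=el.get("displayName", ""),
                    bbox=_bbox_of(el, f"compartment[{el.get('id')}]"),
                    contained_glyph_ids=tuple(
                        c.get("ref", "") for c in el.findall("contains")
                    ),
                )
            )
        elif el.tag == "node":
            gid = el.get("id", "")
            graph_ref = el.get("graphRef")
            nodes.append(
                Glyph(
                    id=gid,
                    render_class=el.get("renderClass", "other"),
                    display_name=el.get("displayName", ""),
                    bbox=_bbox_of(el, f"node[{gid}]"),
                    graph_ref=None if graph_ref in (None, gid) else graph_ref,
                    attachments=tuple(a.get("mark", "") for a in el.findall("attachment")),
                    stoichiometry=int(el.get("stoichiometry", "1")),
                )
            )
        elif el.tag == "edge":
            eid = el.get("id", "")
            graph_ref = el.get("graphRef")
            shape_el = el.find("reactionShape")
            if shape_el is None:
                raise ValidationError("missing <reactionShape>", f"edge[{eid}]")
            edges.append(
                ReactionEdge(
                    id=eid,
                    segments=tuple(
                        Segment(*(
                            _float_attr(s, k, f"edge[{eid}].segment")
                            for k in ("x1", "y1", "x2", "y2")
                        ))
                        for s in el.findall("segment")
                    ),
                    reaction_shape=ReactionShape(
                        _float_attr(shape_el, "x", f"edge[{eid}].reactionShape"),
                        _float_attr(shape_el, "y", f"edge[{eid}].reactionShape"),
                        shape_el.get("kind", "transition"),
                    ),
                    connectors=tuple(
                        Connector(
                            role=c.get("role", ""),
                            glyph_id=c.get("glyphId", ""),
                            stoichiometry=int(c.get("stoichiometry", "1")),
                        )
                        for c in el.findall("connector")
                    ),
                    graph_ref=None if graph_ref in (None, eid) else graph_ref,
                )
            )
    layout = DiagramLayout(
        pathway_id=root.get("pathwayId", ""),
        canvas=_bbox_of(canvas_el, "canvas"),
        compartments=tuple(compartments),
        nodes=tuple(nodes),
        edges=tuple(edges),
    )
    layout.validate()
    return layout


def convert_legacy_xml(source) -> bytes:
    """Convert a legacy XML layout to its JSON serialization (UTF-8 bytes)."""
    return dumps_layout(parse_legacy_xml(source)).encode("utf-8")
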
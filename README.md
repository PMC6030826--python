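# pathglyph

A headless engine for interactive biological pathway diagrams, built for
people who develop or study pathway visualization tools: it implements, as a
testable Python library with a CLI, the data structures and strategies that
make a modern web pathway-diagram viewer fast — without any browser.

Pathway diagrams (SBGN process-description style) draw molecules, complexes
and reactions. Two properties make them hard to serve interactively:

1. **The drawing is not the content.** A macromolecular complex or an entity
   set is drawn as a *single glyph*, but may contain arbitrarily nested
   constituents that are never drawn. A search for protein P must highlight
   every complex C with P ∈ leaves(C), where
   `leaves(C) = ∪_{c ∈ children(C)} leaves(c)` over the acyclic composition
   relation.
2. **Hit-testing and redrawing must not be O(n).** Finding the element under
   the pointer by exhaustive scan, or redrawing the whole scene on every
   hover, makes large diagrams feel unresponsive.

pathglyph addresses both with the architecture of a modern viewer:

- **Dual JSON format** — per pathway, a *layout* file (positioned glyphs,
  reaction edges, compartments) and a *graph* file (full composition +
  reaction participation, including undrawn entities), with validating
  readers/writers, JSON-Schema contracts under `schemas/`, and a legacy-XML
  converter (the JSON serialization is strictly smaller than the XML one).
- **Merged context** — bidirectional glyph ↔ entity maps supporting leaf
  expansion, ancestor collection, search over invisible constituents, and
  halo computation (all reactions touching any instance of a selected
  entity, plus their participants).
- **QuadTree spatial index** — recursive 4-way partition over points *and*
  shapes; point lookup descends one quadrant per level (O(log n) quadrant
  comparisons) and tests only co-located candidates; region queries drive
  viewport culling.
- **Multi-layer LOD renderer** — four stacked layers (compartments, halo,
  nodes & edges, selection & highlight); hover changes regenerate only the
  top layer, selection changes only halo + top layer; zoom thresholds gate
  detail (house-keeping molecules such as ATP/ADP/water are hidden zoomed
  out; labels, decorators, rounded corners, attachments, stoichiometry appear
  progressively). Deterministic SVG/PNG output.
- **Render-first loading + LRU cache** — layout and graph are requested
  concurrently and the first paint happens as soon as the layout arrives;
  revisited pathways are restored from a least-recently-used cache with
  their exact camera state.

## Worked example

The repository ships a two-reaction pathway (`fixtures/fig1.*`): R1 binds
P1 + P2 into complex C1; R2 associates C1 with C2 = [P3, P4, SM1, SM2] into
C3 = [C1, C2]. The drawing shows 7 elements (5 glyphs + 2 edges); the graph
carries 11 (9 entities + 2 reactions) — the 4 extra are C2's constituents,
which have no glyphs. Searching for the undrawn protein P3 highlights the
complexes that contain it:

```bash
$ pathglyph search fixtures/fig1 P3
{"graphId": "P3", "matchField": "id", "highlight": ["C2", "C3"]}
```

A second fixture (`fixtures/fig4.layout.json`) holds nine point-like
elements whose capacity-2 quadtree nests three levels deep around element
P3. Probing the pointer position over P3 costs three quadrant comparisons
and one candidate test — not nine:

```bash
$ pathglyph query fixtures/fig4.layout.json --at 5,55 --stats
{"hits": ["P3"], "stats": {"quadrantComparisons": 3, "candidatesTested": 1}}
```

The loading simulator shows the render-first ordering — the first paint at
t = 0.1 s does not wait for the slower graph (t = 0.5 s):

```bash
$ pathglyph stats fixtures/fig1 --layout-delay 0.1 --graph-delay 0.5
{"events": [{"kind": "layout_requested", "sequence": 1, "time": 0.0},
            {"kind": "graph_requested",  "sequence": 2, "time": 0.0},
            {"kind": "layout_loaded",    "sequence": 3, "time": 0.1},
            {"kind": "first_render",     "sequence": 4, "time": 0.1},
            {"kind": "graph_loaded",     "sequence": 5, "time": 0.5},
            {"kind": "context_merged",   "sequence": 6, "time": 0.5}],
 "cache": {"size": 1, "capacity": 5}}
```

Other subcommands: `pathglyph render <layout> --graph <graph> --zoom 1.5
--select C1 -o out.svg`, `pathglyph convert legacy.xml`, `pathglyph
fixtures --out DIR`, `pathglyph generate --seed 7 --out DIR`.

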
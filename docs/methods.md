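# Methods

This note documents the models, conventions and numerical choices behind
pathglyph, and what its synthetic tests do and do not demonstrate.

## Data model and coordinate conventions

A pathway is shipped as a *layout* (drawable geometry) and a *graph*
(semantic content). The two are deliberately asymmetric: every drawn node
and edge must resolve — via its `graphRef`, defaulting to its own id — to a
graph entity or reaction, while the graph may carry arbitrarily many
entities with no glyph (complex components and set members collapsed into a
single glyph). `validate_pair` treats an unresolved glyph as an error and an
undrawn graph entity as expected information.

Coordinates are real-valued diagram units, y-down, origin at the canvas
top-left, matching screen-canvas convention. Bounding boxes are half-open,
`[x, x+w) × [y, y+h)`. Half-openness is load-bearing in two places: quadrant
descent (a point on a center axis belongs to exactly one child) and
hit-testing (adjacent boxes never double-claim a boundary point). A
zero-area box models a point and "contains" only its own coordinate.

Ids are opaque strings, unique per file; cross-file identity is exact string
match. Stoichiometry defaults to 1 and attachments to empty, and the JSON
writer omits fields holding their default, which keeps hand-written fixtures
terse and the canonical serialization compact. Element counts are
`|nodes| + |edges|` (layout) and `|entities| + |reactions|` (graph);
compartments are framing, not elements.

The composition relation (`children`) must be acyclic; validation delegates
the check to networkx and reports the offending cycle. The legacy XML
dialect (element per glyph, attribute per scalar) is defined by this
artifact to exercise the format-size and conversion properties; its writer
emits every field explicitly, as legacy serializers did, and the converter
is exactly `parse → validate → canonical JSON`.

## Overlay traversals and search

`leaf_participants` and `containing_ancestors` are iterative set-based
closures over `children` and its inverse; diamond-shaped membership (one
entity reachable along several paths) is de-duplicated because the contract
is a set, not a multiset. Search is case-insensitive substring over
displayName *and* id of every graph entity, visible or not. Match semantics
and hit ordering are artifact-defined where the behaviour of production
viewers is unspecified: exact matches first, then earliest match position,
then lexicographic id — chosen purely so results are deterministic and
testable. Halo computation is entity-level: selecting one glyph instance
expands to all instances of its entity, collects every reaction edge whose
connectors touch any instance, and returns those edges plus all their
participant glyphs (catalysts and regulators count as participants). Halos
do not extend transitively to reactions of containing complexes; the scan
stops at direct connector references.

## QuadTree

Capacity (default 2) counts only *point* items in a leaf; exceeding it
splits the leaf and redistributes. Shapes are stored at the deepest node
whose region fully contains them — a shape straddling a split boundary lives
once in an internal node, never duplicated into leaves, so queries need no
de-duplication and shapes cannot force infinite splitting. Quadrants are
numbered Q1–Q4 = top-left, top-right, bottom-left, bottom-right.

A maximum depth (default 12) caps recursion: coincident or near-coincident
points would otherwise split forever; at the cap a leaf may exceed capacity.
Point lookup instrumentation counts one quadrant comparison per internal
node on the descent path and one candidate test per item box examined; the
scaling test asserts the practical consequence of O(log n) behaviour — the
mean candidate count at 10 000 uniform points is below twice the mean at
100 — rather than fitting a curve, because leaf occupancy under uniform
placement is essentially scale-free.

The nine-element worked example uses artifact-chosen coordinates on a
100×100 canvas (quadrant loads 2/2/3/2 at the root; the overfull bottom-left
quadrant nests twice so P3 is alone in the innermost top-left leaf), frozen
in `fixtures/fig4.layout.json` so the 3-comparison/1-candidate lookup is
bit-stable.

## Renderer

Four layers in fixed compositing order: compartments, halo, nodes & edges,
selection & highlight. The dirty-layer contract is the core correctness
property: `update_interaction` regenerates only the layers a state change
can affect (hover → top layer; selection → halo + top layer), re-using the
untouched layers' primitive tuples by identity, and the result must be
primitive-identical to a full re-render of the final state. Tests verify
this over random interaction walks.

Level-of-detail profiles map zoom thresholds to *added* feature sets, so the
active set is a union and monotonicity in zoom holds by construction. The
default cut-offs (0.5: labels + reaction decorators; 1.0: rounded corners +
trivial molecules; 2.0: attachments + stoichiometry) are placeholders — the
production values of deployed viewers are not published — and are
configurable via a JSON profile. Trivial ("house-keeping") molecules are
identified by a configurable display-name list (ATP, ADP, AMP, H2O/water,
Pi, NAD+, NADH) restricted to chemical glyphs.

Primitives are emitted in sorted element order and carry their source
element id as a tag, so tests can assert on content rather than pixels.
SVG output is hand-serialized deterministic text (camera transform applied
as a group transform); PNG rasterizes the same primitives through Pillow.
Byte-determinism of both is asserted.

## Session

Sources are modelled as suppliers with injectable simulated delays; the
contract is the event ordering, not a threading mechanism. Render-first
issues both requests before either completes, emits `first_render`
immediately after `layout_loaded` regardless of graph progress, and
`context_merged` after both. The sequential baseline renders only after
everything loaded; the difference of the two `first_render` times is the
perceived-loading-time saving the acceptance script reports. A graph-source
failure degrades to a layout-only context after a `graph_failed` warning
event (rendering works, search/halo see an empty graph); a layout failure is
fatal. The LRU cache (default capacity 5, configurable; in-memory only) uses
a logical access counter for determinism and stores the camera state, which
a revisit restores exactly.

## Synthetic generator

The generator emulates a mid-sized curated pathway drawing: by default 12
leaf molecules (2 of them house-keeping chemicals), 4 complexes and 2 sets
nested up to depth 3, 5 reactions, and 30% of complex/set constituents left
undrawn — the regime in which the invisible-constituent machinery actually
matters. Acyclicity holds by construction (containers only adopt children
from strictly earlier generations); glyphs sit on a jittered grid sized so
boxes cannot overlap; everything derives from one `random.Random(seed)`, so
equal seeds give byte-identical files. The manifest records the exact
element/invisible counts the output must exhibit, which the tests check by
re-loading the serialized files.

What the generator does *not* emulate: real curated layout aesthetics
(orthogonal edge routing, compartment nesting, label placement), skewed
real-world size distributions (the corpus tail of thousand-element
diagrams), or identifier semantics of external databases. Passing tests
therefore demonstrate the correctness of the data structures and contracts
at realistic small-to-medium scale, not wall-clock performance on a
production corpus; scale behaviour is covered only by the sub-linear
candidate-growth property up to 10 000 indexed points.

## Problem sizes and determinism

The shipped suite and acceptance script use: 51 diagrams for the format-size
comparison, 500 point probes and 200 region probes against the brute-force
oracle on 800 mixed items, 300-probe means at n ∈ {100, 10 000} for scaling,
100 interaction walks of length 4–5 for the dirty-layer contract, 100 delay
schedules for loading order, and a 1000-operation LRU trace — sizes chosen
so every property is exercised far past its corner cases while the whole
suite stays interactive-fast. All randomness flows from explicit seeds
(`--seed` in the acceptance script); hypothesis tests run derandomized.

## Known limitations

- No interactive event loop; interaction is replayed as state transitions.
- Text metrics are nominal: SVG labels use fixed font sizes and no layout
  or wrapping; PNG text rendering uses Pillow's default bitmap font.
- The legacy XML dialect is a defined stand-in, not a reverse-engineered
  historical format; conversion fidelity is proven against it only.
- Search is substring-based; no fuzzy matching, ranking by molecule type,
  or cross-diagram (whole-database) search.
- The cache does not persist across processes.
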
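"""Render-first loading orchestration and the LRU diagram cache.

Loading a pathway needs two resources — the layout and the semantic graph —
which become available independently.  The viewer session requests both at
once and renders as soon as the *layout* arrives; the graph is linked in
whenever it completes.  The observable contract is the event ordering: both
``*_requested`` events precede either completion, ``first_render`` directly
follows ``layout_loaded`` without waiting on the graph, and
``context_merged`` follows ``graph_loaded``.  A sequential baseline (load
everything, then render) is provided for comparison; the gap between the two
``first_render`` times is the perceived-loading-time improvement.

Revisited pathways are served from a least-recently-used cache holding the
merged context together with the camera state the user left it in, so a
reopened diagram shows up instantly, exactly as it was.

Sources are modelled as independently completing suppliers with injectable
delays; any scheduler satisfying the event ordering is a valid
implementation, and the simulated clock keeps everything deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

from .model import DiagramError, DiagramGraph, DiagramLayout, load_graph, load_layout
from .overlay import DiagramContext, merge
from .render import CameraState

__all__ = [
    "EVENT_KINDS",
    "LoadError",
    "LoadEvent",
    "StubSource",
    "CacheEntry",
    "LRUCache",
    "cache_get",
    "cache_put",
    "ViewerSession",
    "layout_only_context",
]

EVENT_KINDS = (
    "layout_requested",
    "graph_requested",
    "layout_loaded",
    "first_render",
    "graph_loaded",
    "graph_failed",
    "context_merged",
)


class LoadError(DiagramError):
    """The layout source failed; nothing can be shown."""


@dataclass(frozen=True)
class LoadEvent:
    kind: str
    pathway_id: str
    sequence: int
    time: float  # simulated seconds since the open started


@dataclass
class StubSource:
    """A delayed supplier of a layout or graph.

    ``payload`` may be the object itself, a path/stream consumable by the
    loaders, or a zero-argument callable producing either.  ``delay`` is the
    simulated seconds until the resource is available; ``fails`` makes the
    supplier raise instead.
    """

    payload: object = None
    delay: float = 0.0
    fails: bool = False

    def get(self, loader: Callable) -> object:
        if self.fails:
            raise IOError("source failed")
        payload = self.payload() if callable(self.payload) else self.payload
        if isinstance(payload, (DiagramLayout, DiagramGraph)):
            return payload
        return loader(payload)


def layout_only_context(layout: DiagramLayout) -> DiagramContext:
    """Degraded context when the graph source failed: rendering works,
    search/halo see an empty semantic graph."""
    return DiagramContext(
        layout=layout,
        graph=DiagramGraph(pathway_id=layout.pathway_id),
        glyph_to_entity={},
        entity_to_glyphs={},
        parents={},
    )


# ---------------------------------------------------------------------------
# LRU cache
# ---------------------------------------------------------------------------


@dataclass
class CacheEntry:
    pathway_id: str
    context: DiagramContext
    camera: CameraState
    last_access: int = 0


class LRUCache:
    """Least-recently-used cache of diagram contexts keyed by pathway id.

    ``last_access`` is a logical counter (not wall clock) so eviction order
    is fully deterministic; both get and put count as an access.
    """

    def __init__(self, capacity: int = 5):
        if capacity < 1:
            raise ValueError(f"cache capacity must be >= 1, got {capacity}")
        self.capacity = capacity
        self.entries: dict[str, CacheEntry] = {}
        self._clock = 0

    def _tick(self) -> int:
        self._clock += 1
        return self._clock

    def get(self, pathway_id: str) -> Optional[CacheEntry]:
        entry = self.entries.get(pathway_id)
        if entry is not None:
            entry.last_access = self._tick()
        return entry

    def put(self, entry: CacheEntry) -> Optional[str]:
        """Store (or refresh) an entry; returns the evicted pathway id when
        the capacity bound forces one out."""
        entry.last_access = self._tick()
        self.entries[entry.pathway_id] = entry
        if len(self.entries) <= self.capacity:
            return None
        victim = min(self.entries.values(), key=lambda e: e.last_access)
        del self.entries[victim.pathway_id]
        return victim.pathway_id

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries


def cache_get(cache: LRUCache, pathway_id: str) -> Optional[CacheEntry]:
    return cache.get(pathway_id)


def cache_put(cache: LRUCache, entry: CacheEntry) -> Optional[str]:
    return cache.put(entry)


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------


class ViewerSession:
    """Orchestrates diagram opens with an event log and the LRU cache.

    ``strategy`` selects render-first (concurrent requests, render on layout
    arrival) or the sequential baseline (request graph only after the layout
    finished, render only after both) — the latter exists to make the
    loading-time difference measurable.
    """

    def __init__(self, cache_capacity: int = 5, strategy: str = "render_first"):
        if strategy not in ("render_first", "sequential"):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.cache = LRUCache(cache_capacity)
        self.strategy = strategy
        self.events: list[LoadEvent] = []
        self._sequence = 0

    # -- events ------------------------------------------------------------
    def _emit(self, kind: str, pathway_id: str, time: float) -> LoadEvent:
        self._sequence += 1
        ev = LoadEvent(kind=kind, pathway_id=pathway_id, sequence=self._sequence, time=time)
        self.events.append(ev)
        return ev

    # -- open --------------------------------------------------------------
    def open_diagram(
        self,
        pathway_id: str,
        layout_source: StubSource | None = None,
        graph_source: StubSource | None = None,
    ) -> tuple[DiagramContext, list[LoadEvent]]:
        """Open a pathway, returning its context and the events of this open.

        A cache hit issues no requests and restores the stored camera (see
        :meth:`camera_of`).  A graph-source failure degrades to a layout-only
        context after a ``graph_failed`` warning event; a layout-source
        failure is fatal.
        """
        start = len(self.events)
        cached = self.cache.get(pathway_id)
        if cached is not None:
            self._emit("first_render", pathway_id, 0.0)
            return cached.context, self.events[start:]
        if layout_source is None or graph_source is None:
            raise LoadError(f"pathway {pathway_id!r} not cached and no sources given")
        if self.strategy == "render_first":
            context = self._open_render_first(pathway_id, layout_source, graph_source)
        else:
            context = self._open_sequential(pathway_id, layout_source, graph_source)
        self.cache.put(CacheEntry(pathway_id, context, CameraState()))
        return context, self.events[start:]

    def _open_render_first(
        self, pathway_id: str, layout_source: StubSource, graph_source: StubSource
    ) -> DiagramContext:
        # both requests go out before either completes
        self._emit("layout_requested", pathway_id, 0.0)
        self._emit("graph_requested", pathway_id, 0.0)
        layout: DiagramLayout | None = None
        graph: DiagramGraph | None = None
        graph_failed = False
        # completions replayed in simulated-time order; ties resolve to the
        # layout, whose arrival is what unblocks the first paint
        completions = sorted(
            (("layout", layout_source), ("graph", graph_source)),
            key=lambda kv: (kv[1].delay, kv[0] != "layout"),
        )
        t_done = max(layout_source.delay, graph_source.delay)
        for role, source in completions:
            if role == "layout":
                try:
                    layout = source.get(load_layout)
                except IOError as exc:
                    raise LoadError(f"layout source for {pathway_id!r} failed") from exc
                self._emit("layout_loaded", pathway_id, source.delay)
                self._emit("first_render", pathway_id, source.delay)
            else:
                try:
                    graph = source.get(load_graph)
                    self._emit("graph_loaded", pathway_id, source.delay)
                except IOError:
                    graph_failed = True
                    self._emit("graph_failed", pathway_id, source.delay)
        if graph_failed:
            return layout_only_context(layout)
        context = merge(layout, graph)
        self._emit("context_merged", pathway_id, t_done)
        return context

    def _open_sequential(
        self, pathway_id: str, layout_source: StubSource, graph_source: StubSource
    ) -> DiagramContext:
        self._emit("layout_requested", pathway_id, 0.0)
        try:
            layout = layout_source.get(load_layout)
        except IOError as exc:
            raise LoadError(f"layout source for {pathway_id!r} failed") from exc
        self._emit("layout_loaded", pathway_id, layout_source.delay)
        self._emit("graph_requested", pathway_id, layout_source.delay)
        t_graph = layout_source.delay + graph_source.delay
        try:
            graph = graph_source.get(load_graph)
            self._emit("graph_loaded", pathway_id, t_graph)
            context = merge(layout, graph)
            self._emit("context_merged", pathway_id, t_graph)
        except IOError:
            self._emit("graph_failed", pathway_id, t_graph)
            context = layout_only_context(layout)
        self._emit("first_render", pathway_id, t_graph)
        return context

    # -- camera ------------------------------------------------------------
    def update_camera(self, pathway_id: str, camera: CameraState) -> None:
        """Record the user's view state so a revisit restores it."""
        entry = self.cache.entries.get(pathway_id)
        if entry is None:
            raise LoadError(f"pathway {pathway_id!r} is not cached")
        entry.camera = camera

    def camera_of(self, pathway_id: str) -> CameraState:
        entry = self.cache.entries.get(pathway_id)
        if entry is None:
            raise LoadError(f"pathway {pathway_id!r} is not cached")
        return entry.camera

    # -- introspection -----------------------------------------------------
    def first_render_time(self, events: list[LoadEvent]) -> float:
        for ev in events:
            if ev.kind == "first_render":
                return ev.time
        raise LoadError("no first_render event in trace")
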
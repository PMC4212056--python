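"""Multirelational graph container with ordered adjacency and relation bitmasks.

A :class:`MultiGraph` stores, for every vertex, a sorted list of neighbors
together with a pair of relation bitmasks per neighbor: the *forward* mask
records relations on the edge oriented away from the vertex, the *backward*
mask records relations oriented toward it.  For undirected graphs the two
masks coincide.  Bit ``k`` of a mask set means relation ``k+1`` is present;
a mask of zero means no connection, which the profile machinery treats as a
connection type in its own right.

Self-loops are not representable: loop input lines are dropped with a
warning.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MultiGraph",
    "Event",
    "EventStream",
    "read_edgelist",
    "write_edgelist",
    "read_events",
    "write_events",
    "from_events",
]


class MultiGraph:
    """Undirected or directed multirelational graph on 0-based vertex ids.

    Parameters
    ----------
    num_vertices:
        Number of vertices; ids are ``0 .. num_vertices-1``.
    directed:
        Whether edge direction is tracked.  Undirected graphs keep
        ``forward == backward`` on every adjacency entry.
    num_relations:
        Number of relation types ``r >= 1``; masks are integers in
        ``[0, 2**r)``.
    """

    def __init__(self, num_vertices: int, directed: bool = False,
                 num_relations: int = 1):
        if num_vertices < 0:
            raise ValueError("num_vertices must be nonnegative")
        if num_relations < 1:
            raise ValueError("num_relations must be >= 1")
        self.num_vertices = num_vertices
        self.directed = bool(directed)
        self.num_relations = num_relations
        # per-vertex parallel sorted arrays: neighbor ids, forward masks,
        # backward masks
        self._nbrs: list[list[int]] = [[] for _ in range(num_vertices)]
        self._fwd: list[list[int]] = [[] for _ in range(num_vertices)]
        self._bwd: list[list[int]] = [[] for _ in range(num_vertices)]

    # -- construction -----------------------------------------------------

    def _entry(self, i: int, j: int) -> int:
        """Index of j in i's adjacency, inserting a zero entry if absent."""
        nbrs = self._nbrs[i]
        pos = bisect_left(nbrs, j)
        if pos == len(nbrs) or nbrs[pos] != j:
            nbrs.insert(pos, j)
            self._fwd[i].insert(pos, 0)
            self._bwd[i].insert(pos, 0)
        return pos

    def add_edge(self, i: int, j: int, relation: int = 1) -> None:
        """Add relation ``relation`` (1-based) on the edge from i to j.

        For undirected graphs the edge is symmetric; for directed graphs it
        is oriented i -> j.  Repeated additions OR into the existing masks.
        """
        self._check_vertex(i)
        self._check_vertex(j)
        if i == j:
            raise ValueError("self-loops are not supported")
        if not 1 <= relation <= self.num_relations:
            raise ValueError(
                f"relation {relation} out of range [1, {self.num_relations}]")
        bit = 1 << (relation - 1)
        pi = self._entry(i, j)
        pj = self._entry(j, i)
        self._fwd[i][pi] |= bit
        self._bwd[j][pj] |= bit
        if not self.directed:
            self._bwd[i][pi] |= bit
            self._fwd[j][pj] |= bit

    # -- queries ----------------------------------------------------------

    def _check_vertex(self, v: int) -> None:
        if not 0 <= v < self.num_vertices:
            raise IndexError(f"vertex id {v} out of range")

    def degree(self, v: int) -> int:
        self._check_vertex(v)
        return len(self._nbrs[v])

    def neighbors(self, v: int) -> Sequence[int]:
        """Sorted neighbor ids of ``v`` (union of directions if directed)."""
        self._check_vertex(v)
        return self._nbrs[v]

    def adjacency(self, v: int) -> tuple[Sequence[int], Sequence[int], Sequence[int]]:
        """Parallel sorted arrays ``(neighbors, forward, backward)`` for v."""
        self._check_vertex(v)
        return self._nbrs[v], self._fwd[v], self._bwd[v]

    def relation_mask(self, i: int, j: int) -> tuple[int, int]:
        """Forward/backward relation masks for the ordered query (i, j).

        Returns ``(0, 0)`` when no edge exists.  Lookup is a binary search
        in the adjacency of the lower-degree endpoint.
        """
        self._check_vertex(i)
        self._check_vertex(j)
        if i == j:
            raise ValueError("relation_mask requires i != j")
        if len(self._nbrs[i]) <= len(self._nbrs[j]):
            nbrs = self._nbrs[i]
            pos = bisect_left(nbrs, j)
            if pos == len(nbrs) or nbrs[pos] != j:
                return (0, 0)
            return (self._fwd[i][pos], self._bwd[i][pos])
        nbrs = self._nbrs[j]
        pos = bisect_left(nbrs, i)
        if pos == len(nbrs) or nbrs[pos] != i:
            return (0, 0)
        return (self._bwd[j][pos], self._fwd[j][pos])

    def has_edge(self, i: int, j: int) -> bool:
        f, b = self.relation_mask(i, j)
        return bool(f | b)

    @property
    def num_edges(self) -> int:
        """Number of unordered pairs carrying any relation in any direction."""
        return sum(len(n) for n in self._nbrs) // 2

    def edges(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield ``(i, j, forward, backward)`` for every unordered pair i<j."""
        for i in range(self.num_vertices):
            nbrs, fwd, bwd = self._nbrs[i], self._fwd[i], self._bwd[i]
            for pos, j in enumerate(nbrs):
                if j > i:
                    yield i, j, fwd[pos], bwd[pos]

    def copy(self) -> "MultiGraph":
        g = MultiGraph(self.num_vertices, self.directed, self.num_relations)
        g._nbrs = [list(x) for x in self._nbrs]
        g._fwd = [list(x) for x in self._fwd]
        g._bwd = [list(x) for x in self._bwd]
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiGraph):
            return NotImplemented
        return (self.num_vertices == other.num_vertices
                and self.directed == other.directed
                and self.num_relations == other.num_relations
                and self._nbrs == other._nbrs
                and self._fwd == other._fwd
                and self._bwd == other._bwd)

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return (f"MultiGraph({self.num_vertices} vertices, "
                f"{self.num_edges} edges, r={self.num_relations}, {kind})")


# -- event streams --------------------------------------------------------

@dataclass(frozen=True)
class Event:
    source: int
    target: int
    timestamp: float
    relation: Optional[int] = None


@dataclass
class EventStream:
    """Timestamped edge events; sources differ from targets, ties allowed."""

    records: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.records:
            if e.source == e.target:
                raise ValueError("event stream contains a self-loop event")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.records)

    def timestamps(self) -> list[float]:
        return [e.timestamp for e in self.records]

    def span(self) -> tuple[float, float]:
        ts = self.timestamps()
        if not ts:
            raise ValueError("empty event stream has no span")
        return min(ts), max(ts)

    def max_vertex(self) -> int:
        return max(max(e.source, e.target) for e in self.records)


def from_events(stream: EventStream, window: tuple[float, float],
                num_vertices: Optional[int] = None,
                directed: bool = False) -> MultiGraph:
    """Unirelational union graph of all events in the half-open window.

    Repeated events collapse to one edge.  ``num_vertices`` defaults to
    ``max id + 1`` over the whole stream; an empty stream with no explicit
    vertex count is an error.
    """
    if num_vertices is None:
        if not stream.records:
            raise ValueError("cannot infer vertex count from an empty stream")
        num_vertices = stream.max_vertex() + 1
    start, end = window
    g = MultiGraph(num_vertices, directed=directed, num_relations=1)
    for e in stream:
        if start <= e.timestamp < end:
            g.add_edge(e.source, e.target, 1)
    return g


# -- plain-text readers and writers ---------------------------------------

def _tokenize(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.replace(",", " ").split()


def read_edgelist(path, directed: bool = False, num_relations: int = 1,
                  relation_column: bool = False,
                  num_vertices: Optional[int] = None) -> MultiGraph:
    """Read a whitespace/comma-delimited edge list into a MultiGraph.

    Columns are ``src dst [relation]``; ``#`` comment lines are skipped.
    Extra columns (e.g. weights) are accepted and ignored.  Duplicate lines
    and multiple relation lines for one pair merge by OR-ing masks.
    Self-loop lines are dropped with a logged warning.
    """
    rows: list[tuple[int, int, int]] = []
    max_id = -1
    for lineno, toks in _tokenize(path):
        need = 3 if relation_column else 2
        if len(toks) < need:
            raise ValueError(f"{path}:{lineno}: expected at least {need} columns")
        try:
            src, dst = int(toks[0]), int(toks[1])
            rel = int(toks[2]) if relation_column else 1
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line") from exc
        if src == dst:
            logger.warning("%s:%d: dropping self-loop %d-%d", path, lineno, src, dst)
            continue
        if not 1 <= rel <= num_relations:
            raise ValueError(
                f"{path}:{lineno}: relation {rel} out of range [1, {num_relations}]")
        rows.append((src, dst, rel))
        max_id = max(max_id, src, dst)
    if num_vertices is None:
        num_vertices = max_id + 1
    g = MultiGraph(num_vertices, directed=directed, num_relations=num_relations)
    for src, dst, rel in rows:
        g.add_edge(src, dst, rel)
    return g


def write_edgelist(graph: MultiGraph, path) -> None:
    """Write sorted, deduplicated edge lines, one per (pair, relation).

    Directed graphs emit a line per oriented (src, dst, relation); undirected
    graphs one line per unordered pair and relation with src < dst.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# vcp edgelist directed={int(graph.directed)} "
                 f"r={graph.num_relations} vertices={graph.num_vertices}\n")
        for i, j, fwd, bwd in graph.edges():
            for k in range(graph.num_relations):
                bit = 1 << k
                if fwd & bit:
                    fh.write(f"{i}\t{j}\t{k + 1}\n")
                if graph.directed and (bwd & bit):
                    fh.write(f"{j}\t{i}\t{k + 1}\n")


def read_events(path) -> EventStream:
    """Read ``src dst timestamp [relation]`` lines into an EventStream."""
    records = []
    for lineno, toks in _tokenize(path):
        if len(toks) < 3:
            raise ValueError(f"{path}:{lineno}: expected src dst timestamp")
        try:
            src, dst, ts = int(toks[0]), int(toks[1]), float(toks[2])
            rel = int(toks[3]) if len(toks) > 3 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line") from exc
        if src == dst:
            logger.warning("%s:%d: dropping self-loop event", path, lineno)
            continue
        records.append(Event(src, dst, ts, rel))
    return EventStream(records)


def write_events(stream: EventStream, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in stream:
            rel = "" if e.relation is None else f"\t{e.relation}"
            fh.write(f"{e.source}\t{e.target}\t{e.timestamp:g}{rel}\n")
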
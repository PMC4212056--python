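"""Temporal-snapshot encoding of longitudinal event streams.

An event stream is divided into contiguous half-open *chunks*; consecutive
chunks are grouped into *snapshots*; and each snapshot becomes one relation
of a multirelational graph, so that a pair's relation bitmask records in
which periods the pair interacted.  Relation 1 is the OLDEST snapshot and
the highest relation the most recent, so recency occupies the high bits.

Two grouping schemes are supported: equal (chunks split as evenly as
possible, the oldest snapshot absorbing any remainder) and exponential
(the newest snapshot spans 2 chunks, each older one doubles, and the
oldest absorbs the deficit or surplus) — the latter concentrates relational
resolution on recent events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graphcore import Event, EventStream, MultiGraph

__all__ = [
    "SnapshotSpec",
    "chunk_boundaries",
    "snapshot_spec",
    "snapshot_encode",
    "reorder_events",
]


@dataclass(frozen=True)
class SnapshotSpec:
    """Ordered boundaries t_0 < ... < t_p defining p half-open snapshots."""

    boundaries: tuple[float, ...]
    scheme: str = "equal"

    def __post_init__(self):
        bs = self.boundaries
        if len(bs) < 2:
            raise ValueError("need at least two boundaries")
        if any(a >= b for a, b in zip(bs, bs[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if self.scheme not in ("equal", "exponential"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def num_snapshots(self) -> int:
        return len(self.boundaries) - 1

    def snapshot_of(self, ts: float) -> Optional[int]:
        """0-based snapshot index of a timestamp (oldest = 0), or None."""
        bs = self.boundaries
        if ts < bs[0] or ts >= bs[-1]:
            return None
        # snapshots are few; linear scan is fine
        for k in range(len(bs) - 1):
            if bs[k] <= ts < bs[k + 1]:
                return k
        return None


def chunk_boundaries(stream: EventStream, k: int,
                     mode: str = "by-time") -> list[float]:
    """Divide a stream's span into k contiguous half-open chunks.

    by-time: equal-duration intervals spanning [min ts, max ts]; the last
    boundary is nudged just past the maximum so the final chunk includes it.
    by-count: near-equal event counts with boundaries at timestamp changes.
    """
    if k < 1:
        raise ValueError("chunk count must be >= 1")
    if not stream.records:
        raise ValueError("cannot chunk an empty stream")
    tmin, tmax = stream.span()
    if mode == "by-time":
        if tmax == tmin:
            return [float(tmin), math.nextafter(float(tmax), math.inf)]
        bounds = [tmin + i * (tmax - tmin) / k for i in range(k + 1)]
        bounds[-1] = math.nextafter(float(tmax), math.inf)
        return [float(b) for b in bounds]
    if mode == "by-count":
        ts = np.sort(np.asarray(stream.timestamps(), dtype=float))
        distinct, counts = np.unique(ts, return_counts=True)
        if k > len(distinct):
            raise ValueError(
                f"cannot form {k} chunks from {len(distinct)} distinct timestamps")
        cum = np.cumsum(counts)
        m = len(ts)
        bounds = [float(distinct[0])]
        prev_cut = 0
        for q in range(1, k):
            target = q * m / k
            # candidate cuts between distinct timestamps, after the previous
            lo = prev_cut + 1
            hi = len(distinct) - (k - q)  # leave room for remaining chunks
            cand = range(lo, hi + 1)
            cut = min(cand, key=lambda c: (abs(cum[c - 1] - target), c))
            bounds.append(float(distinct[cut]))
            prev_cut = cut
        bounds.append(math.nextafter(float(distinct[-1]), math.inf))
        return bounds
    raise ValueError(f"unknown chunking mode {mode!r}")


def snapshot_sizes(num_chunks: int, periods: int, scheme: str) -> list[int]:
    """Chunks per snapshot, oldest first; sizes sum to num_chunks."""
    if periods < 1 or periods > num_chunks:
        raise ValueError("periods must be in [1, number of chunks]")
    if scheme == "equal":
        base, rem = divmod(num_chunks, periods)
        sizes = [base] * periods
        sizes[0] += rem  # oldest absorbs the remainder
        return sizes
    if scheme == "exponential":
        # newest snapshot = 2 chunks, doubling toward the past; the oldest
        # absorbs whatever deficit or surplus remains
        newer = [2 * 2 ** i for i in range(periods - 1)]  # newest first
        oldest = num_chunks - sum(newer)
        if oldest < 1:
            raise ValueError(
                f"{num_chunks} chunks cannot fill {periods} exponential periods")
        return [oldest] + newer[::-1]
    raise ValueError(f"unknown scheme {scheme!r}")


def snapshot_spec(chunks: list[float], periods: int,
                  scheme: str = "equal") -> SnapshotSpec:
    """Group chunk boundaries into snapshot boundaries."""
    num_chunks = len(chunks) - 1
    sizes = snapshot_sizes(num_chunks, periods, scheme)
    bounds = [chunks[0]]
    at = 0
    for size in sizes:
        at += size
        bounds.append(chunks[at])
    return SnapshotSpec(tuple(bounds), scheme)


def snapshot_encode(stream: EventStream, spec: SnapshotSpec,
                    num_vertices: Optional[int] = None,
                    directed: bool = False) -> MultiGraph:
    """Encode the snapshot in which each event occurs as its relation type.

    Produces a graph with r = number of snapshots; an event in snapshot k
    (0-based, oldest first) sets relation k+1.  Events outside all
    snapshots are ignored; repeated in-snapshot events collapse.
    """
    if num_vertices is None:
        if not stream.records:
            raise ValueError("cannot infer vertex count from an empty stream")
        num_vertices = stream.max_vertex() + 1
    g = MultiGraph(num_vertices, directed=directed,
                   num_relations=spec.num_snapshots)
    for e in stream:
        k = spec.snapshot_of(e.timestamp)
        if k is not None:
            g.add_edge(e.source, e.target, k + 1)
    return g


def reorder_events(stream: EventStream, seed: int) -> EventStream:
    """Randomly reassign the stream's timestamps to its (source, target) pairs.

    The multiset of timestamps and the multiset of pairs are both
    preserved; only their association is permuted, destroying any genuine
    temporal ordering while leaving the time-aggregated union graph
    untouched.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    ts = stream.timestamps()
    perm = rng.permutation(len(ts))
    records = [Event(e.source, e.target, ts[perm[i]], e.relation)
               for i, e in enumerate(stream.records)]
    records.sort(key=lambda e: e.timestamp)
    return EventStream(records)
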
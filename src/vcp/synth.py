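"""Synthetic graph and event-stream generators.

Three generators:

* :func:`adversarial_er` — a multirelational Erdős–Rényi variant designed
  as a worst case for profile sparsity: moderate density plus random
  relation placement maximizes the diversity of observed isomorphism
  classes, which is exactly the regime where profile vectors are densest.
* :func:`random_multigraph` — a generic seeded random graph (independent
  relation/direction placement) used to drive oracle-equivalence suites.
* :func:`longitudinal_synth` — an event stream with a tunable tendency for
  new events to close recently formed wedges, so that temporally resolved
  features carry predictive signal that survives only under the true event
  ordering.  This stream generator is test machinery for the pipeline, not
  a model of any particular real system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphcore import Event, EventStream, MultiGraph
from .isomap import UniverseSpec
from .profiles import profile_pairs

__all__ = [
    "AdversarialERParams",
    "adversarial_er",
    "random_multigraph",
    "element_population",
    "longitudinal_synth",
]


@dataclass(frozen=True)
class AdversarialERParams:
    """Parameters of the adversarial multirelational ER model.

    ``p_edge`` is the classical G(n, p) parameter, but here it only makes a
    pair a *candidate* for relational population; each of the r relations
    is then placed independently with probability ``p_rel``.  A candidate
    may end up with no relations at all, so p_edge = 1 does not imply a
    complete graph unless p_rel = 1.
    """

    num_vertices: int
    r: int
    p_edge: float
    p_rel: float
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.p_edge <= 1.0 and 0.0 <= self.p_rel <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


def adversarial_er(params: AdversarialERParams) -> MultiGraph:
    """Sample the adversarial multirelational ER model (undirected)."""
    rng = np.random.default_rng(params.seed)
    nv, r = params.num_vertices, params.r
    g = MultiGraph(nv, directed=False, num_relations=r)
    for i in range(nv):
        for j in range(i + 1, nv):
            if rng.random() < params.p_edge:
                for k in range(r):
                    if rng.random() < params.p_rel:
                        g.add_edge(i, j, k + 1)
    return g


def random_multigraph(num_vertices: int, p: float, num_relations: int = 1,
                      directed: bool = False, seed: int = 0) -> MultiGraph:
    """Seeded ER-style graph: each (pair, relation, direction) independent."""
    rng = np.random.default_rng(seed)
    g = MultiGraph(num_vertices, directed=directed,
                   num_relations=num_relations)
    for i in range(num_vertices - 1):
        m = num_vertices - i - 1
        for k in range(num_relations):
            for j in i + 1 + np.nonzero(rng.random(m) < p)[0]:
                g.add_edge(i, int(j), k + 1)
            if directed:
                for j in i + 1 + np.nonzero(rng.random(m) < p)[0]:
                    g.add_edge(int(j), i, k + 1)
    return g


def element_population(graph: MultiGraph, spec: UniverseSpec,
                       mapping=None) -> int:
    """Number of distinct profile elements populated over ALL vertex pairs."""
    pairs = [(i, j) for i in range(graph.num_vertices)
             for j in range(i + 1, graph.num_vertices)]
    seen: set[int] = set()
    for vec in profile_pairs(graph, pairs, n=spec.n, mapping=mapping):
        seen.update(vec.counts)
    return len(seen)


def longitudinal_synth(num_vertices: int, chunks: int, events_per_chunk: int,
                       recency_bias: float = 0.0, seed: int = 0,
                       closure_fraction: float = 0.6) -> EventStream:
    """Event stream whose wedge closures prefer recently built wedges.

    Each chunk contributes exactly ``events_per_chunk`` events with
    timestamps uniform in [chunk, chunk+1).  A fraction of events
    (``closure_fraction``, when open wedges exist) close a distance-2 pair,
    sampled with weight exp(recency_bias * m / chunks), where m is the
    pair's *wedge recency*: over all common neighbors, the best of
    min(latest activity chunk of the two wedge edges).  Wedge recency is
    exactly the quantity a chunk-granular snapshot encoding of the stream
    can express, so with a high bias the relation structure around a pair
    genuinely predicts closure — and only under the true event ordering.
    With recency_bias = 0 the closure choice is uniform over open
    distance-2 pairs, independent of history timing.  Remaining events pick
    uniform random pairs.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    adj: dict[int, set[int]] = {v: set() for v in range(num_vertices)}
    last_chunk: dict[tuple[int, int], int] = {}   # edge -> latest event chunk
    recency: dict[tuple[int, int], int] = {}      # open pair -> wedge recency
    records: list[Event] = []

    def key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def touch(u: int, v: int, ts: float) -> None:
        c = int(ts)
        records.append(Event(u, v, ts))
        new_edge = v not in adj[u]
        adj[u].add(v)
        adj[v].add(u)
        last_chunk[key(u, v)] = c
        if new_edge:
            recency.pop(key(u, v), None)
        # refresh wedge recency of every open pair routed through this edge
        for a, b in ((u, v), (v, u)):
            for w in adj[b]:
                if w != a and w not in adj[a]:
                    k = key(a, w)
                    fresh = min(c, last_chunk[key(b, w)])
                    if recency.get(k, -1) < fresh:
                        recency[k] = fresh

    def sample_closure():
        if not recency:
            return None
        pairs = list(recency)
        m = np.fromiter(recency.values(), dtype=float, count=len(pairs))
        w = np.exp(recency_bias * m / chunks)
        w /= w.sum()
        return pairs[int(rng.choice(len(pairs), p=w))]

    for chunk in range(chunks):
        offsets = np.sort(rng.random(events_per_chunk))
        for off in offsets:
            ts = chunk + float(off)
            pair = None
            if rng.random() < closure_fraction:
                pair = sample_closure()
            if pair is None:
                while True:
                    u, v = rng.integers(0, num_vertices, size=2)
                    if u != v:
                        break
                pair = (int(u), int(v))
            touch(pair[0], pair[1], ts)
    return EventStream(records)
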
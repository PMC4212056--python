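"""Per-pair vertex collocation profile (VCP) counting.

For a fixed pair (v_s, v_t), the n-vertex VCP vector counts, for every
selection of n-2 free vertices, the isomorphism class of the induced
subgraph on (v_s, v_t, free vertices).  Two families of algorithms are
provided:

* naive oracles (:func:`vcp3_naive`, :func:`vcp4_naive`) that enumerate
  every free-vertex selection in the whole graph — transparent, slow,
  and used as the ground truth the optimized routines are tested against;
* neighborhood algorithms (:func:`vcp3`, :func:`vcp4`) that touch only the
  sorted adjacencies of v_s, v_t and their neighbors, and recover the
  counts of structures with unobserved free vertices by closed-form
  corrections from a handful of per-graph aggregates.

Both produce sparse element -> count maps.  Counts always conserve mass:
they sum to |V|-2 for n=3 and C(|V|-2, 2) for n=4.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from .graphcore import MultiGraph
from .isomap import DynamicMapping, ElementMapping, UniverseSpec

logger = logging.getLogger(__name__)

__all__ = [
    "VCPVector",
    "Vcp4Accumulators",
    "vcp3_naive",
    "vcp3",
    "vcp4_naive",
    "vcp4",
    "profile_pairs",
    "write_profiles",
]

Mapping = Union[ElementMapping, DynamicMapping, None]

#: beyond this many relations the detached-substructure relation resolution
#: is disabled and detached elements are omitted from output
DETACHED_RELATION_LIMIT = 16


@dataclass
class VCPVector:
    """Sparse element -> count vector for one vertex pair."""

    pair: tuple[int, int]
    spec: UniverseSpec
    counts: dict[int, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_line(self) -> str:
        cells = " ".join(f"{e}:{c}" for e, c in sorted(self.counts.items()))
        return f"{self.pair[0]}\t{self.pair[1]}\t{cells}"


@dataclass
class Vcp4Accumulators:
    """Aggregates maintained by the optimized n=4 counter.

    alpha/beta count directly observed connected/unconnected free-vertex
    pairs, gamma counts vertices exactly two hops from the pair, and the
    global edge/gap totals feed the closed-form corrections for structures
    never visited by the neighborhood scan.  ``ops`` tallies neighbor-touch
    operations and exposes the neighborhood-bound cost of the algorithm.
    """

    alpha: int = 0
    beta: int = 0
    gamma: int = 0
    global_edges: int = 0
    global_gaps: int = 0
    ops: int = 0


def _element_lookup(mapping: Mapping):
    if mapping is None:
        return lambda addr: addr
    return mapping.element_of


def _cell(graph: MultiGraph, a: int, b: int) -> int:
    """Cell value for the ordered label pair (lower, higher) = (a, b)."""
    f, bkw = graph.relation_mask(a, b)
    if graph.directed:
        return f | (bkw << graph.num_relations)
    return f


def _flip(cell: int, r: int) -> int:
    """Exchange forward/backward sub-blocks of a directed cell value."""
    fm = (1 << r) - 1
    return ((cell & fm) << r) | (cell >> r)


def _check_spec(graph: MultiGraph, spec: UniverseSpec, n: int) -> None:
    if spec.n != n:
        raise ValueError(f"mapping spec has n={spec.n}, expected {n}")
    if spec.r != graph.num_relations or spec.directed != graph.directed:
        raise ValueError("universe spec does not match graph (r, d)")


# -- n = 3 ----------------------------------------------------------------

def vcp3_naive(graph: MultiGraph, s: int, t: int,
               mapping: Mapping = None,
               spec: Optional[UniverseSpec] = None) -> VCPVector:
    """Enumerate every third vertex in the graph.  O(|V|) edge searches."""
    spec = spec or (mapping.spec if mapping else
                    UniverseSpec(3, graph.num_relations, graph.directed))
    _check_spec(graph, spec, 3)
    if s == t:
        raise ValueError("s and t must differ")
    o12, o13, o23 = spec.offsets()
    elem = _element_lookup(mapping)
    base = _cell(graph, s, t) << o12
    counts: dict[int, int] = {}
    for k in range(graph.num_vertices):
        if k == s or k == t:
            continue
        addr = base | (_cell(graph, s, k) << o13) | (_cell(graph, t, k) << o23)
        e = elem(addr)
        counts[e] = counts.get(e, 0) + 1
    return VCPVector((s, t), spec, counts)


def vcp3(graph: MultiGraph, s: int, t: int,
         mapping: Mapping = None,
         spec: Optional[UniverseSpec] = None,
         omit_detached: bool = False) -> VCPVector:
    """Single merged scan of the sorted adjacencies of s and t.

    Identical output to :func:`vcp3_naive`; the count of fully detached
    third vertices is obtained arithmetically instead of by iteration.
    """
    spec = spec or (mapping.spec if mapping else
                    UniverseSpec(3, graph.num_relations, graph.directed))
    _check_spec(graph, spec, 3)
    if s == t:
        raise ValueError("s and t must differ")
    o12, o13, o23 = spec.offsets()
    elem = _element_lookup(mapping)
    base = _cell(graph, s, t) << o12
    counts: dict[int, int] = {}
    r = graph.num_relations
    ns, fs, bs = graph.adjacency(s)
    nt, ft, bt = graph.adjacency(t)
    i = j = 0
    observed = 0
    while i < len(ns) or j < len(nt):
        if j >= len(nt) or (i < len(ns) and ns[i] <= nt[j]):
            k = ns[i]
        else:
            k = nt[j]
        c13 = c23 = 0
        if i < len(ns) and ns[i] == k:
            c13 = fs[i] | (bs[i] << r) if graph.directed else fs[i]
            i += 1
        if j < len(nt) and nt[j] == k:
            c23 = ft[j] | (bt[j] << r) if graph.directed else ft[j]
            j += 1
        if k == s or k == t:
            continue
        observed += 1
        addr = base | (c13 << o13) | (c23 << o23)
        e = elem(addr)
        counts[e] = counts.get(e, 0) + 1
    detached = graph.num_vertices - 2 - observed
    if detached > 0 and not omit_detached:
        e = elem(base)
        counts[e] = counts.get(e, 0) + detached
    return VCPVector((s, t), spec, counts)


# -- n = 4 ----------------------------------------------------------------

def vcp4_naive(graph: MultiGraph, s: int, t: int,
               mapping: Mapping = None,
               spec: Optional[UniverseSpec] = None) -> VCPVector:
    """Enumerate every unordered pair of free vertices.  O(|V|^2) searches.

    Intended as a test oracle for graphs up to a few hundred vertices.
    """
    spec = spec or (mapping.spec if mapping else
                    UniverseSpec(4, graph.num_relations, graph.directed))
    _check_spec(graph, spec, 4)
    if s == t:
        raise ValueError("s and t must differ")
    if mapping is None:
        mapping = DynamicMapping(spec)  # n=4 addresses need canonicalizing
    o12, o13, o14, o23, o24, o34 = spec.offsets()
    elem = _element_lookup(mapping)
    base = _cell(graph, s, t) << o12
    counts: dict[int, int] = {}
    frees = [v for v in range(graph.num_vertices) if v != s and v != t]
    for a, k in enumerate(frees):
        c13 = _cell(graph, s, k) << o13
        c23 = _cell(graph, t, k) << o23
        for l in frees[a + 1:]:
            addr = (base | c13 | c23
                    | (_cell(graph, s, l) << o14)
                    | (_cell(graph, t, l) << o24)
                    | (_cell(graph, k, l) << o34))
            e = elem(addr)
            counts[e] = counts.get(e, 0) + 1
    return VCPVector((s, t), spec, counts)


def edge_combo_counts(graph: MultiGraph) -> Counter:
    """Frequency of each relation combination over all edges.

    Keys are cell values oriented lower-vertex-id -> higher-vertex-id; used
    to resolve the relation combinations of edges between free vertices
    never visited by the neighborhood scan.
    """
    r = graph.num_relations
    table: Counter = Counter()
    for i, j, fwd, bwd in graph.edges():
        table[fwd | (bwd << r) if graph.directed else fwd] += 1
    return table


def _merged_neighborhood(graph: MultiGraph, s: int, t: int):
    """Sorted union of the neighborhoods of s and t (excluding s, t).

    Returns parallel lists: vertex ids, cell values toward s, toward t.
    """
    r = graph.num_relations
    ns, fs, bs = graph.adjacency(s)
    nt, ft, bt = graph.adjacency(t)
    ids: list[int] = []
    c_s: list[int] = []
    c_t: list[int] = []
    i = j = 0
    while i < len(ns) or j < len(nt):
        if j >= len(nt) or (i < len(ns) and ns[i] <= nt[j]):
            k = ns[i]
        else:
            k = nt[j]
        cs = ct = 0
        if i < len(ns) and ns[i] == k:
            cs = fs[i] | (bs[i] << r) if graph.directed else fs[i]
            i += 1
        if j < len(nt) and nt[j] == k:
            ct = ft[j] | (bt[j] << r) if graph.directed else ft[j]
            j += 1
        if k != s and k != t:
            ids.append(k)
            c_s.append(cs)
            c_t.append(ct)
    return ids, c_s, c_t


def vcp4(graph: MultiGraph, s: int, t: int,
         mapping: Mapping = None,
         spec: Optional[UniverseSpec] = None,
         omit_detached: bool = False,
         combo_counts: Optional[Counter] = None,
         stats: Optional[Vcp4Accumulators] = None) -> VCPVector:
    """Neighborhood algorithm for n=4; output identical to :func:`vcp4_naive`.

    Structure: an outer loop over the merged neighborhood N of s and t and,
    per member k, one merged inner scan of N and the adjacency of k.  The
    scan fully observes every structure whose free vertices both touch
    {s, t} or lie within two hops; three closed-form corrections then
    account for the rest:

    * per k, structures whose fourth vertex is isolated number
      |V| - 2 - |N| - |two-hop neighbors of k|;
    * free pairs detached from s and t but connected to each other number
      |E| minus the edges encountered directly, resolved per relation
      combination by decrementing a copy of the global combination table;
    * the remaining detached, unconnected free pairs are the total pair
      budget minus everything counted above.

    Never iterates over all of V; cost is bounded by neighborhood sizes.
    """
    spec = spec or (mapping.spec if mapping else
                    UniverseSpec(4, graph.num_relations, graph.directed))
    _check_spec(graph, spec, 4)
    if s == t:
        raise ValueError("s and t must differ")
    if mapping is None:
        mapping = DynamicMapping(spec)  # n=4 addresses need canonicalizing
    if spec.r > DETACHED_RELATION_LIMIT and not omit_detached:
        logger.info("r=%d exceeds detached-resolution limit %d; "
                    "omitting detached substructures", spec.r,
                    DETACHED_RELATION_LIMIT)
        omit_detached = True

    o12, o13, o14, o23, o24, o34 = spec.offsets()
    elem = _element_lookup(mapping)
    r = graph.num_relations
    directed = graph.directed
    nv = graph.num_vertices
    acc = stats if stats is not None else Vcp4Accumulators()
    acc.global_edges = graph.num_edges
    acc.global_gaps = nv * (nv - 1) // 2 - acc.global_edges

    c12 = _cell(graph, s, t)
    base = c12 << o12
    counts: dict[int, int] = {}

    def bump(addr: int, by: int = 1) -> None:
        e = elem(addr)
        counts[e] = counts.get(e, 0) + by

    ids, c_s, c_t = _merged_neighborhood(graph, s, t)
    pos = {v: a for a, v in enumerate(ids)}
    n_obs = len(ids)
    n_far = nv - 2 - n_obs  # vertices adjacent to neither s nor t

    track_combos = not omit_detached
    combos: Counter = Counter()
    if track_combos:
        combos = Counter(combo_counts if combo_counts is not None
                         else edge_combo_counts(graph))
        if c12:
            combos[c12 if s < t or not directed else _flip(c12, r)] -= 1

    for a, k in enumerate(ids):
        b13 = c_s[a] << o13
        b23 = c_t[a] << o23
        if track_combos:
            if c_s[a]:
                combos[c_s[a] if s < k or not directed else _flip(c_s[a], r)] -= 1
            if c_t[a]:
                combos[c_t[a] if t < k or not directed else _flip(c_t[a], r)] -= 1
        nk, fk, bk = graph.adjacency(k)
        two_hop = 0
        # merged scan of N and the adjacency of k
        i = j = 0
        while i < n_obs or j < len(nk):
            acc.ops += 1
            if j >= len(nk) or (i < n_obs and ids[i] <= nk[j]):
                u = ids[i]
            else:
                u = nk[j]
            c34 = 0
            in_nk = False
            if j < len(nk) and nk[j] == u:
                c34 = fk[j] | (bk[j] << r) if directed else fk[j]
                in_nk = True
                j += 1
            in_obs = False
            if i < n_obs and ids[i] == u:
                in_obs = True
                i += 1
            if u == s or u == t:
                continue
            if in_obs:
                if u > k:
                    # both free vertices observed: full structure
                    bu = pos[u]
                    addr = (base | b13 | b23
                            | (c_s[bu] << o14) | (c_t[bu] << o24)
                            | (c34 << o34))
                    bump(addr)
                    if c34:
                        acc.alpha += 1
                        if track_combos:
                            combos[c34] -= 1  # oriented k -> u with k < u
                    else:
                        acc.beta += 1
            elif in_nk:
                # u is two hops out: attached to k only
                two_hop += 1
                acc.gamma += 1
                bump(base | b13 | b23 | (c34 << o34))
                acc.alpha += 1
                if track_combos:
                    combos[c34 if k < u or not directed else _flip(c34, r)] -= 1
        # fourth vertex isolated: neither s, t, k nor any of k's neighbors
        isolated = n_far - two_hop
        if isolated > 0:
            bump(base | b13 | b23, isolated)

    if not omit_detached:
        # free pairs detached from s and t: connected ones resolved per
        # relation combination, the unconnected remainder lands on the
        # base element
        detached_edges = 0
        for cell, m in combos.items():
            if m > 0 and cell:
                detached_edges += m
                bump(base | (cell << o34), m)
        detached_gaps = n_far * (n_far - 1) // 2 - detached_edges
        if detached_gaps > 0:
            bump(base, detached_gaps)
    return VCPVector((s, t), spec, counts)


# -- batch driver ---------------------------------------------------------

def profile_pairs(graph: MultiGraph, pairs: Iterable[tuple[int, int]],
                  n: int = 4, mapping: Mapping = None,
                  omit_detached: bool = False) -> Iterator[VCPVector]:
    """Compute VCP vectors for a batch of pairs, sharing per-graph work.

    The global relation-combination table is built once and copied per
    pair.  Output order matches input pair order.  With ``omit_detached``
    set, elements whose subgraphs attach neither free vertex to s or t are
    suppressed; all other counts are unchanged.
    """
    if n == 3:
        for s, t in pairs:
            yield vcp3(graph, s, t, mapping, omit_detached=omit_detached)
    elif n == 4:
        spec = mapping.spec if mapping else UniverseSpec(
            4, graph.num_relations, graph.directed)
        if mapping is None:
            mapping = DynamicMapping(spec)  # shared memo across the batch
        combos = None
        if not omit_detached and spec.r <= DETACHED_RELATION_LIMIT:
            combos = edge_combo_counts(graph)
        for s, t in pairs:
            yield vcp4(graph, s, t, mapping, omit_detached=omit_detached,
                       combo_counts=combos)
    else:
        raise ValueError("optimized profiles support n in {3, 4}")


def write_profiles(vectors: Iterable[VCPVector], path,
                   spec: Optional[UniverseSpec] = None) -> None:
    """Write one ``src<TAB>dst<TAB>e1:c1 e2:c2 ...`` line per pair."""
    from .isomap import LAYOUT_VERSION
    with open(path, "w", encoding="utf-8") as fh:
        first = True
        for vec in vectors:
            if first:
                sp = spec or vec.spec
                fh.write(f"# vcp-profiles n={sp.n} r={sp.r} d={sp.d} "
                         f"shift_st={int(sp.shift_st)} layout={LAYOUT_VERSION}\n")
                first = False
            fh.write(vec.to_line() + "\n")
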
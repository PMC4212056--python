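"""Subgraph-universe addressing and free-vertex canonicalization.

A *subgraph universe* ``G^{n,r,d}`` is the set of all labeled n-vertex
subgraphs over r relations with directionality d in {0, 1}.  Vertex labels
1 and 2 denote the fixed source/target pair (v_s, v_t); labels 3..n are
*free* vertices.  Each unordered vertex pair holds a cell of
``(d+1)*r`` bits (for directed universes: the low r bits encode relations
oriented lower-label -> higher-label, the high r bits the reverse), and the
cells are packed into an integer *address* with significance increasing in
lexicographic pair order from e_{1,2} to e_{n-1,n}.

Permuting the free vertices while fixing v_s and v_t partitions the
universe into isomorphism classes; the minimum address in each class is its
canonical representative and identifies one element of the vertex
collocation profile (VCP) vector.  This module enumerates those classes
(statically, as a full address->element vector) or resolves them lazily
(dynamically, via a memoized map), and cross-checks class counts against a
Burnside orbit count derived from permutation cycle structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "UniverseSpec",
    "universe_size",
    "cell_weights",
    "address",
    "decode_address",
    "free_vertex_permutations",
    "permuted_address",
    "canonical_address",
    "ElementMapping",
    "build_static_mapping",
    "DynamicMapping",
    "vcp_cardinality",
    "burnside_cardinality",
    "write_mapping",
    "read_mapping",
]

STATIC_CAP = 2 ** 24  # largest universe enumerated as a full vector

LAYOUT_VERSION = 1


@dataclass(frozen=True)
class UniverseSpec:
    """An (n, r, d) subgraph universe.

    Parameters
    ----------
    n:
        Number of subgraph vertices, >= 3.
    r:
        Number of relations, >= 1.
    directed:
        Directionality flag d.
    shift_st:
        Move the s-t cell e_{1,2} to the *most* significant position so
        that, for non-adjacent prediction pairs, populated elements cluster
        in the low half of the vector.  Off by default; all worked examples
        assume the default layout.
    """

    n: int
    r: int
    directed: bool = False
    shift_st: bool = False

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("universe needs n >= 3 vertices")
        if self.r < 1:
            raise ValueError("universe needs r >= 1 relations")

    @property
    def d(self) -> int:
        return int(self.directed)

    @property
    def bits_per_cell(self) -> int:
        return (self.d + 1) * self.r

    @property
    def num_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def address_bits(self) -> int:
        return self.bits_per_cell * self.num_pairs

    @property
    def cell_mask(self) -> int:
        return (1 << self.bits_per_cell) - 1

    def pairs(self) -> list[tuple[int, int]]:
        """Unordered vertex pairs (0-based labels) in lexicographic order."""
        n = self.n
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def offsets(self) -> list[int]:
        """Bit offset of each pair's cell, in pair order."""
        bpc = self.bits_per_cell
        offs = [bpc * k for k in range(self.num_pairs)]
        if self.shift_st:
            # e_{1,2} takes the top cell; every other cell drops one slot
            offs = [offs[-1]] + offs[:-1]
        return offs


def universe_size(spec: UniverseSpec) -> int:
    """|G^{n,r,d}| = 2**((d+1) * r * n(n-1)/2), exact."""
    return 1 << spec.address_bits


def cell_weights(spec: UniverseSpec) -> list[int]:
    """Significance weight 2**offset of each pair's cell, in pair order."""
    return [1 << o for o in spec.offsets()]


def address(cells: Sequence[int], spec: UniverseSpec) -> int:
    """Pack per-pair cell values into a subgraph address.

    ``cells[k]`` is the relation value of the k-th lexicographic pair; for
    directed universes it is ``forward | (backward << r)`` with *forward*
    oriented lower-label -> higher-label.
    """
    if len(cells) != spec.num_pairs:
        raise ValueError(f"expected {spec.num_pairs} cells, got {len(cells)}")
    addr = 0
    mask = spec.cell_mask
    for c, off in zip(cells, spec.offsets()):
        if not 0 <= c <= mask:
            raise ValueError(f"cell value {c} exceeds {mask}")
        addr |= c << off
    return addr


def decode_address(addr: int, spec: UniverseSpec) -> list[int]:
    """Inverse of :func:`address`."""
    if not 0 <= addr < universe_size(spec):
        raise ValueError("address out of range for universe")
    mask = spec.cell_mask
    return [(addr >> off) & mask for off in spec.offsets()]


def free_vertex_permutations(spec: UniverseSpec) -> Iterator[tuple[int, ...]]:
    """All (n-2)! images of the free vertex labels 2..n-1 (0-based).

    Labels 0 and 1 (v_s, v_t) are never permuted: isomorphisms that map the
    source onto the target do not merge VCP elements.
    """
    return itertools.permutations(range(2, spec.n))


def _cell_moves(spec: UniverseSpec,
                perm: tuple[int, ...]) -> list[tuple[int, int, bool]]:
    """Per-cell relocation plan for a free-vertex permutation.

    Returns (source offset, destination offset, endpoint swap flag) per
    pair; the swap flag marks cells whose endpoints reverse order, which in
    directed universes exchanges the forward and backward sub-blocks.
    """
    full = {0: 0, 1: 1}
    for k, image in enumerate(perm):
        full[2 + k] = image
    pairs = spec.pairs()
    rank = {p: k for k, p in enumerate(pairs)}
    offs = spec.offsets()
    moves = []
    for k, (i, j) in enumerate(pairs):
        pi, pj = full[i], full[j]
        swapped = pi > pj
        dst = rank[(pj, pi) if swapped else (pi, pj)]
        moves.append((offs[k], offs[dst], swapped))
    return moves


def permuted_address(addr: int, perm: tuple[int, ...],
                     spec: UniverseSpec) -> int:
    """Address of the subgraph relabeled by a free-vertex permutation."""
    mask = spec.cell_mask
    r = spec.r
    fwd_mask = (1 << r) - 1
    out = 0
    for src, dst, swapped in _cell_moves(spec, perm):
        cell = (addr >> src) & mask
        if swapped and spec.directed:
            cell = ((cell & fwd_mask) << r) | (cell >> r)
        out |= cell << dst
    return out


def canonical_address(addr: int, spec: UniverseSpec) -> int:
    """Minimum address over all free-vertex permutations of the subgraph."""
    return min(permuted_address(addr, p, spec)
               for p in free_vertex_permutations(spec))


# -- element mappings -----------------------------------------------------

class ElementMapping:
    """Static subgraph-address -> contiguous element-index map.

    Built by enumerating the whole universe, canonicalizing every address,
    and numbering the distinct canonical representatives 0, 1, ... in
    increasing canonical-address order.  Lookup is a constant-time vector
    read.
    """

    mode = "static"

    def __init__(self, spec: UniverseSpec, canon: np.ndarray,
                 reps: np.ndarray):
        self.spec = spec
        self._canon = canon       # address -> canonical address
        self._reps = reps         # sorted distinct canonical addresses
        self._index = {int(c): i for i, c in enumerate(reps)}

    @property
    def num_elements(self) -> int:
        return len(self._reps)

    def canonical_of(self, addr: int) -> int:
        return int(self._canon[addr])

    def element_of(self, addr: int) -> int:
        """Contiguous 0-based element index of the address's class."""
        return self._index[int(self._canon[addr])]

    def element_canonical(self, index: int) -> int:
        """Canonical address identifying element ``index``."""
        return int(self._reps[index])

    def orbit_sizes(self) -> np.ndarray:
        """Class sizes in element order; they sum to the universe size."""
        _, counts = np.unique(self._canon, return_counts=True)
        return counts


def build_static_mapping(spec: UniverseSpec,
                         cap: int = STATIC_CAP) -> ElementMapping:
    """Enumerate the universe and canonicalize every address.

    Vectorized: each free-vertex permutation is applied to all addresses at
    once as a sequence of shift/mask cell moves, and the canonical map is
    the elementwise minimum across permutations.  Refuses universes larger
    than ``cap`` (use dynamic mode there).
    """
    size = universe_size(spec)
    if size > cap:
        raise ValueError(
            f"universe size {size} exceeds static cap {cap}; "
            "use DynamicMapping for this spec")
    addrs = np.arange(size, dtype=np.uint64)
    best = addrs.copy()
    mask = np.uint64(spec.cell_mask)
    r = spec.r
    fwd_mask = np.uint64((1 << r) - 1)
    for perm in free_vertex_permutations(spec):
        moves = _cell_moves(spec, perm)
        if all(src == dst and not sw for src, dst, sw in moves):
            continue  # identity
        out = np.zeros(size, dtype=np.uint64)
        for src, dst, swapped in moves:
            cell = (addrs >> np.uint64(src)) & mask
            if swapped and spec.directed:
                cell = ((cell & fwd_mask) << np.uint64(r)) | (cell >> np.uint64(r))
            out |= cell << np.uint64(dst)
        np.minimum(best, out, out=best)
    reps = np.unique(best)
    return ElementMapping(spec, best, reps)


class DynamicMapping:
    """Memoized address -> canonical-address map for arbitrarily large universes.

    Element ids are the (non-contiguous) canonical addresses themselves,
    carried as arbitrary-precision integers.  On first observation of an
    address the whole (n-2)!-member orbit is computed and memoized, so
    subsequent lookups anywhere in the orbit are pure map reads.
    """

    mode = "dynamic"

    def __init__(self, spec: UniverseSpec):
        self.spec = spec
        self._memo: dict[int, int] = {}

    def element_of(self, addr: int) -> int:
        memo = self._memo
        hit = memo.get(addr)
        if hit is not None:
            return hit
        orbit = {permuted_address(addr, p, self.spec)
                 for p in free_vertex_permutations(self.spec)}
        canon = min(orbit)
        for member in orbit:
            memo[member] = canon
        return canon

    canonical_of = element_of

    @property
    def num_memoized(self) -> int:
        return len(self._memo)

    @property
    def num_elements(self) -> int:
        """Distinct canonical representatives observed so far."""
        return len(set(self._memo.values()))


def vcp_cardinality(spec: UniverseSpec, cap: int = STATIC_CAP) -> int:
    """Number of VCP elements |VCP^{n,r,d}| by full enumeration."""
    return build_static_mapping(spec, cap=cap).num_elements


def burnside_cardinality(spec: UniverseSpec) -> int:
    """Independent orbit count from permutation cycle structure.

    By Burnside's lemma the number of isomorphism classes equals the
    average, over the free-vertex permutation group, of the number of
    addresses each permutation fixes.  A permutation fixes exactly
    ``(2**r) ** c`` addresses, where c is the number of cycles of its
    induced action on unordered vertex pairs (undirected) or ordered pairs
    (directed): every cell along a cycle must carry the same r-bit value.
    """
    n = spec.n
    if spec.directed:
        cells = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        cells = [(i, j) for i in range(n) for j in range(i + 1, n)]
    total = 0
    for perm in free_vertex_permutations(spec):
        full = {0: 0, 1: 1}
        for k, image in enumerate(perm):
            full[2 + k] = image

        def image_of(cell):
            i, j = full[cell[0]], full[cell[1]]
            if not spec.directed and i > j:
                i, j = j, i
            return (i, j)

        seen = set()
        cycles = 0
        for cell in cells:
            if cell in seen:
                continue
            cycles += 1
            cur = cell
            while cur not in seen:
                seen.add(cur)
                cur = image_of(cur)
        total += (1 << spec.r) ** cycles
    return total // factorial(n - 2)


# -- mapping persistence ---------------------------------------------------

def write_mapping(mapping: ElementMapping, path) -> None:
    """Emit the subgraph -> element table as TSV with a header line."""
    spec = mapping.spec
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# vcp-mapping n={spec.n} r={spec.r} d={spec.d} "
                 f"shift_st={int(spec.shift_st)} layout={LAYOUT_VERSION}\n")
        fh.write("# address\tcanonical\telement\n")
        for addr in range(universe_size(spec)):
            canon = mapping.canonical_of(addr)
            fh.write(f"{addr}\t{canon}\t{mapping._index[canon]}\n")


def read_mapping(path) -> ElementMapping:
    """Reload a mapping written by :func:`write_mapping`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# vcp-mapping"):
            raise ValueError("not a vcp mapping file")
        fields = dict(tok.split("=") for tok in header.split()[2:])
        if int(fields.get("layout", -1)) != LAYOUT_VERSION:
            raise ValueError("unsupported mapping layout version")
        spec = UniverseSpec(n=int(fields["n"]), r=int(fields["r"]),
                            directed=bool(int(fields["d"])),
                            shift_st=bool(int(fields["shift_st"])))
        canon = np.zeros(universe_size(spec), dtype=np.uint64)
        for line in fh:
            if line.startswith("#"):
                continue
            addr, c, _ = line.split()
            canon[int(addr)] = int(c)
    return ElementMapping(spec, canon, np.unique(canon))
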
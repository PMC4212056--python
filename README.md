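# vcp — vertex collocation profiles

Tools for computing **vertex collocation profiles** (VCPs): for a fixed
vertex pair (v<sub>s</sub>, v<sub>t</sub>) in a network, the VCP is a sparse
vector counting how many selections of n−2 further vertices embed the pair
in each isomorphically distinct n-vertex subgraph, over any number of
relations r and with or without edge direction d. VCPs are a
high-resolution alternative to common-neighbor counts, triad censuses and
graphlet degrees for describing *how* two vertices sit together in their
local topology, and they make strong feature vectors for supervised link
prediction. Because multiple relations are native to the formalism, time
can be folded in by encoding longitudinal snapshots as relations.

The package is aimed at network scientists — in systems biology
(protein-interaction and disease-association networks), computational
social science, or any domain where predicting or explaining link formation
matters.

## The objects

* **Subgraph universe** G<sup>n,r,d</sup>: all labeled n-vertex subgraphs;
  its size is 2<sup>(d+1)·r·n(n−1)/2</sup>. Each unordered vertex pair
  contributes one (d+1)·r-bit cell; packing cells in lexicographic pair
  order (e<sub>1,2</sub> least significant) yields an integer **address**
  Ψ for every subgraph.
* **VCP element**: an isomorphism class of subgraphs under permutations of
  the *free* vertices only (v_s and v_t are never interchanged), identified
  by the minimum address over the (n−2)! permutations — the canonical
  representative. For example the 4096-address directed unirelational
  4-vertex universe collapses to 2112 elements, while its undirected
  2-relation counterpart keeps 2176: direction introduces more isomorphic
  equivalence than an extra relation.
* **VCP vector** VCP<sup>n,r,d</sup><sub>s,t</sub>: element → count, with
  the conservation law Σ counts = |V|−2 (n=3) or C(|V|−2, 2) (n=4).

Counting uses either transparent exhaustive enumeration (the test oracles)
or optimized neighborhood algorithms whose work is bounded by the sorted
adjacencies of v_s, v_t and their neighbors — never by |V| — with
closed-form corrections for structures whose free vertices were never
visited.

## Worked example

Six vertices; 0 and 1 are the pair of interest; edges
0–2, 1–2, 0–3, 1–3, 3–4, 0–4:

```python
from vcp import MultiGraph, UniverseSpec, build_static_mapping, vcp4

g = MultiGraph(6)
for a, b in [(0, 2), (1, 2), (0, 3), (1, 3), (3, 4), (0, 4)]:
    g.add_edge(a, b)

mapping = build_static_mapping(UniverseSpec(4, 1, False))
vec = vcp4(g, 0, 1, mapping)
print(vec.to_line())
```

prints

```
0	1	2:1 8:2 12:1 18:1 32:1
```

Reading it: of the C(4, 2) = 6 ways to choose two free vertices, one lands
in element 2 (one free vertex attached to v_s only — here {4, 5}), two in
element 8 (a shared neighbor of both plus an isolate — {2, 5} and {3, 5}),
one in element 12 (canonical address 14: one common neighbor, the other
free vertex tied to v_s — {2, 4}), one in element 18 (canonical address 30:
both free vertices adjacent to both endpoints but not to each other —
{2, 3}), and one in element 32 (canonical address 46: the class where the
two free vertices are also linked to each other — {3, 4}). The counts sum to 6, as they must.

The same machinery runs from the shell:

```
vcp map --n 4 --r 1 --directed 1 --out mapping.tsv   # 2112 elements
vcp profile graph.txt --n 4 --r 2 --ell2 --out profiles.txt
vcp snapshot events.txt --chunks 6 --periods 2 --out temporal.txt
```

For link prediction, `vcp.linkpred` enumerates distance-2 candidate pairs,
builds labeled datasets from temporally ordered feature/label windows (with
a hard leakage guard), undersamples training negatives to 25% positive
prevalence, ranks elements by information gain over ordered value-frequency
maps, trains a bagged random-subspace ensemble, and scores with AUROC and
AUPR. `vcp.temporal` turns event streams into multirelational snapshot
graphs (equal or exponential granularity) and provides the event-reordering
control that separates genuine temporal signal from weight surrogacy.

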
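# Methods

This note records the model underlying the package, the numerical and
design choices that were genuinely open, what the synthetic generators do
and do not emulate, and known limitations.

## Addressing and canonicalization

A subgraph on labeled vertices v₁=v_s, v₂=v_t, v₃…v_n over r relations is
addressed by packing one (d+1)·r-bit cell per unordered vertex pair into an
integer. Cell significance increases in lexicographic pair order from
e₁,₂ (least significant) to e₍n−1₎,n (most significant). In directed
universes each cell holds the forward block (relations oriented lower →
higher label) in its low r bits and the backward block in the high r bits.
A mask of zero is a first-class connection type ("not connected"), which is
why conservation laws hold: every free-vertex selection lands in exactly
one class.

Two conventions here were open and are pinned as follows:

* **Canonical representative = minimum address** over the (n−2)!
  permutations of the free vertices. v_s and v_t are never permuted —
  collapsing them would erase the asymmetry of a source/target pair, which
  is the point of the profile. The minimum convention, together with the
  bit layout above, reproduces all of the worked address identities the
  test suite checks (1364/2388 → 884 directed; 792 and 1336 undirected
  2-relation; the {2, 4} class at element 2; 20 classes with the free–free
  edge set).
* **Static element indices** are 0-based and assigned in increasing
  canonical-address order, so the index table is reproducible from the
  universe alone.

An optional `shift_st` layout moves the s–t cell to the most significant
position, so that for non-adjacent prediction pairs all populated elements
cluster in the low half of the vector and the tail can be truncated. It is
off by default; every documented example uses the default layout.

Static enumeration is vectorized (each permutation is a fixed sequence of
shift/mask cell moves applied to all addresses at once; the canonical map
is the elementwise minimum) and refuses universes larger than 2²⁴
addresses. Beyond the cap, the dynamic mapping canonicalizes addresses
lazily with arbitrary-precision integers and memoizes whole orbits, so
element ids are canonical addresses themselves (unique, not contiguous).
Class counts are cross-checked against a Burnside orbit count computed only
from permutation cycle structure on (ordered or unordered) vertex pairs —
an independent route that shares no code with enumeration.

## Counting algorithms

`vcp3_naive` / `vcp4_naive` enumerate every free-vertex selection in the
whole graph. They are kept as oracles: transparent, exact, and slow.

`vcp3` performs one merged scan of the sorted adjacencies of v_s and v_t;
the count of fully detached third vertices is |V|−2 minus the scanned
union, obtained without touching the rest of the graph.

`vcp4` loops over the merged neighborhood N of v_s and v_t and, for each
member k, runs one merged scan of N and k's adjacency. This directly
observes every structure in which both free vertices touch {v_s, v_t}, and
every two-hop structure (one free vertex in N, the other a neighbor of k
outside N). Three closed-form corrections cover what the scan never
visits:

1. per k, structures whose fourth vertex is isolated number
   |V|−2−|N|−|Γ(k)∖(N ∪ {v_s, v_t})|;
2. detached-but-linked free pairs are the graph's edges minus those
   encountered directly; for r>1 their relation combinations are resolved
   by decrementing a copied global table keyed by the cell value of each
   edge (oriented lower → higher vertex id);
3. the remaining detached, unlinked pairs are the pair budget
   C(|V|−2, 2) minus everything already counted.

Free-vertex pairs are enumerated unordered; isomorphism collapsing then
makes conservation exact (ordered enumeration with halving would break on
fixed-point orbits). Directed neighborhoods use the union of in- and
out-neighbors; induced subgraphs always carry full directional masks.
Beyond r = 16 relations the detached-resolution table is disabled and
detached elements are omitted (with a log notice): the combination table
grows with the number of distinct masks while contributing the least
informative elements. Work is bounded by neighborhood sizes, not |V|; the
test suite asserts this by counting neighbor-touch operations at |V|=1000
vs |V|=4000 under fixed mean degree.

## Temporal encoding

Event streams are cut into contiguous half-open chunks (equal duration, or
near-equal event counts with boundaries at timestamp changes), chunks are
grouped into snapshots, and snapshot membership becomes the relation of an
edge. Conventions: relation 1 is the **oldest** snapshot, so recency
occupies high bits; the final chunk boundary is nudged just past the
maximum timestamp so the last event is included; only the **oldest**
snapshot deviates from its ideal size when chunks do not divide evenly
(it is the snapshot that matters least for prediction). The exponential
scheme sizes the newest snapshot at 2 chunks and doubles backwards —
concentrating relational resolution on recent events — which requires at
least 2+4+1 chunks for three periods.

`reorder_events` is the control for weight surrogacy: it permutes the
assignment of the timestamp multiset to the pair multiset, which preserves
the time-aggregated union graph (and therefore every unirelational
profile) while destroying genuine ordering.

## Synthetic generators

`adversarial_er(num_vertices, r, p_edge, p_rel, seed)` implements the
worst-case profile-sparsity regime: each pair becomes a candidate with
probability p_edge, then each relation is placed independently with
probability p_rel (a candidate can end up unlinked). Moderate density plus
random relation placement maximizes observed class diversity; the tests
assert that all-pairs element population peaks at interior parameter
values and collapses toward the extremes. The population level also
depends strongly on the sample budget |V|·(|V|−1)/2 · C(|V|−2, 2): at
|V|=100 almost every 2-relation class appears even at 15% density, so the
under-half-population check is run at |V|=30 (~71k samples), where
low-density starvation of dense classes is visible.

`longitudinal_synth` emits a stream of `chunks × events_per_chunk` events.
A fraction (0.6 by default) of events close a currently open distance-2
pair sampled with weight exp(recency_bias · m / chunks), where m is the
pair's wedge recency: over its common neighbors, the best of
min(latest-activity chunk of the two wedge edges). Wedge recency is by
construction expressible by a chunk-granular snapshot encoding, so
`recency_bias` directly controls how much signal temporally resolved
features can carry; at 0 the closure choice ignores timing entirely. The
remaining events hit uniform random pairs and act as label noise. This
generator is test machinery, not a fitted model of any real system: it has
no degree heterogeneity, no community structure, no periodicity, and its
closure mechanism is exactly one wedge deep. Passing pipeline tests
therefore show that the machinery recovers a temporal closure signal when
one exists and reports none after reordering — not that any particular
real network behaves this way.

The pipeline experiments are run at |V|=100, 6 chunks × 80 events,
recency_bias 6.0, with training features from chunks 1–4 of the span,
training labels from chunk 5, and the test windows slid one chunk forward —
sizes chosen so the full 10-seed contrast completes in a few minutes on one
CPU while leaving ~1,200 candidate pairs and ~30–50 positives per run.

## Link-prediction pipeline

Candidates are unordered pairs at geodesic distance exactly 2 (directed
graphs are projected for candidacy; features stay directed). Labels come
from a strictly later window; an overlap raises an error rather than a
warning, because temporal leakage silently inflates every downstream
number. Training sets are undersampled to 25% positive prevalence
(positives kept, negatives uniformly subsampled); test sets are never
touched. The classifier is 10 bootstrap bags × 10 decision trees, each
tree on a random half of the feature columns, scored by mean positive
probability; it is configuration, not contract — every acceptance property
is about the controls (permuted-label null at chance, reordering erasing
the temporal advantage), not classifier internals. Feature columns are the
elements populated in training, which filters never-seen elements at zero
cost.

Evaluation is implemented directly: AUROC by the midrank Mann–Whitney
formulation, AUPR as the step-function area of the precision–recall curve
sweeping tied-score groups from the highest score, no interpolation. With
all scores tied these conventions give 0.5 and the positive prevalence
respectively. scikit-learn's metrics are used in tests only, as the
independent cross-check. Seed-level comparisons use a one-sided sign test
(`paired_sign_test`), chosen for distribution-freeness at 10 paired
observations.

## Limitations

* Optimized counting covers n = 3 and n = 4; larger n falls back to
  exhaustive enumeration, exponential in n.
* No closed-form class-count formula is attempted; counts come from
  enumeration with the Burnside count as the only independent check.
* Graphs are in-memory and vertex ids dense; streaming or out-of-core
  graphs are out of scope, as are edge weights (quantize into relations
  instead) and self-loops.
* Parallelism is left to the caller: per-pair computations are independent,
  so sharding a pair list scales linearly.
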
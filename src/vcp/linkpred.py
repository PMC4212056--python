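"""Supervised link prediction with vertex collocation profiles as features.

The pipeline mirrors standard supervised link-prediction practice: candidate
pairs are those at geodesic distance exactly two in the feature graph (the
high-prior set), each pair's sparse profile vector is its feature vector,
labels come from a strictly later label graph, the training set is
undersampled to a target positive prevalence while the test set is left
untouched, and a bagged random-subspace ensemble produces scores evaluated
by AUROC and AUPR (the latter being the more sensitive metric under the
extreme class imbalance typical of link formation).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.stats import binomtest, rankdata

from .graphcore import EventStream, MultiGraph, from_events
from .isomap import UniverseSpec
from .profiles import profile_pairs
from .temporal import chunk_boundaries, snapshot_encode, snapshot_spec

__all__ = [
    "LeakageError",
    "PairDataset",
    "FeatureStats",
    "EvalResult",
    "ModelConfig",
    "ell2_pairs",
    "build_dataset",
    "undersample",
    "info_gain_rank",
    "symmetrize_scores",
    "evaluate",
    "train_predict",
    "paired_sign_test",
    "temporal_experiment",
]


class LeakageError(ValueError):
    """Raised when a label window does not strictly follow its feature window."""


@dataclass
class PairDataset:
    """Labeled rows of (source, target, sparse profile counts, label)."""

    rows: list[tuple[int, int, dict[int, int], int]]
    spec: UniverseSpec
    feature_window: Optional[tuple[float, float]] = None
    label_window: Optional[tuple[float, float]] = None

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def num_positive(self) -> int:
        return sum(lbl for *_, lbl in self.rows)

    @property
    def prevalence(self) -> float:
        return self.num_positive / len(self.rows)

    def labels(self) -> np.ndarray:
        return np.array([lbl for *_, lbl in self.rows], dtype=int)

    def element_ids(self) -> list[int]:
        seen: set[int] = set()
        for _, _, counts, _ in self.rows:
            seen.update(counts)
        return sorted(seen)

    def to_matrix(self, element_ids: Optional[Sequence[int]] = None
                  ) -> tuple[csr_matrix, np.ndarray, list[int]]:
        """Sparse feature matrix over the given element columns."""
        cols = list(element_ids) if element_ids is not None else self.element_ids()
        col_of = {e: i for i, e in enumerate(cols)}
        indptr = [0]
        indices: list[int] = []
        data: list[int] = []
        for _, _, counts, _ in self.rows:
            for e in sorted(counts):
                c = col_of.get(e)
                if c is not None:
                    indices.append(c)
                    data.append(counts[e])
            indptr.append(len(indices))
        X = csr_matrix((data, indices, indptr),
                       shape=(len(self.rows), len(cols)), dtype=float)
        return X, self.labels(), cols


def ell2_pairs(graph: MultiGraph) -> list[tuple[int, int]]:
    """All unordered pairs at geodesic distance exactly two.

    A pair qualifies when it shares at least one common neighbor and is not
    directly linked by any relation in any direction.  Directed graphs are
    treated through their undirected projection (the stored adjacency is
    already the union of directions).  Output is deterministic ascending.
    """
    found: set[tuple[int, int]] = set()
    for v in range(graph.num_vertices):
        nbrs = graph.neighbors(v)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                u, w = nbrs[a], nbrs[b]
                if (u, w) not in found and not graph.has_edge(u, w):
                    found.add((u, w))
    return sorted(found)


def build_dataset(feature_graph: MultiGraph, label_graph: MultiGraph,
                  pairs: Iterable[tuple[int, int]], n: int = 4,
                  mapping=None,
                  feature_window: Optional[tuple[float, float]] = None,
                  label_window: Optional[tuple[float, float]] = None,
                  omit_detached: bool = False) -> PairDataset:
    """One labeled row per pair: profile from the feature graph, label from
    the label graph.

    A positive label means the pair is linked in the label graph and
    unlinked in the feature graph.  If both windows are given, the label
    window must start at or after the feature window's end (hard failure
    otherwise — temporal leakage silently inflates every downstream score).
    """
    if feature_window is not None and label_window is not None:
        if label_window[0] < feature_window[1]:
            raise LeakageError(
                f"label window {label_window} overlaps feature window "
                f"{feature_window}")
    rows = []
    spec = None
    for vec in profile_pairs(feature_graph, list(pairs), n=n, mapping=mapping,
                             omit_detached=omit_detached):
        s, t = vec.pair
        label = int(label_graph.has_edge(s, t)
                    and not feature_graph.has_edge(s, t))
        rows.append((s, t, vec.counts, label))
        spec = vec.spec
    if spec is None:
        spec = UniverseSpec(n, feature_graph.num_relations,
                            feature_graph.directed)
    return PairDataset(rows, spec, feature_window, label_window)


def undersample(ds: PairDataset, positive_prevalence: float = 0.25,
                seed: int = 0) -> PairDataset:
    """Subsample negatives to reach the target positive prevalence.

    All positives are kept; negatives are drawn uniformly without
    replacement.  A dataset already at or above the target is returned
    unchanged.  Row order is preserved.
    """
    if not 0.0 < positive_prevalence <= 1.0:
        raise ValueError("positive_prevalence must be in (0, 1]")
    pos_idx = [i for i, row in enumerate(ds.rows) if row[3] == 1]
    neg_idx = [i for i, row in enumerate(ds.rows) if row[3] == 0]
    if not pos_idx:
        raise ValueError("cannot undersample a dataset with no positives")
    target_neg = round(len(pos_idx) * (1.0 - positive_prevalence)
                       / positive_prevalence)
    if len(neg_idx) <= target_neg:
        return ds
    rng = np.random.default_rng(seed)
    keep_neg = set(rng.choice(len(neg_idx), size=target_neg,
                              replace=False).tolist())
    keep = set(pos_idx) | {neg_idx[i] for i in keep_neg}
    rows = [row for i, row in enumerate(ds.rows) if i in keep]
    return PairDataset(rows, ds.spec, ds.feature_window, ds.label_window)


# -- feature statistics and information gain -------------------------------

@dataclass
class FeatureStats:
    """Per-element ordered value -> frequency maps, split by class.

    The single-pass, non-contiguous counting sort over sparse rows: each
    element's map includes the implicit zero value for rows where the
    element is absent, so per-element frequencies total the dataset size.
    """

    per_element: dict[int, tuple[Counter, Counter]]
    class_totals: tuple[int, int]

    @classmethod
    def from_dataset(cls, ds: PairDataset) -> "FeatureStats":
        n0 = sum(1 for *_, lbl in ds.rows if lbl == 0)
        n1 = len(ds.rows) - n0
        per: dict[int, tuple[Counter, Counter]] = {}
        for _, _, counts, lbl in ds.rows:
            for e, v in counts.items():
                if e not in per:
                    per[e] = (Counter(), Counter())
                per[e][lbl][v] += 1
        # fold in the implicit zeros
        for e, (c0, c1) in per.items():
            z0 = n0 - sum(c0.values())
            z1 = n1 - sum(c1.values())
            if z0:
                c0[0] += z0
            if z1:
                c1[0] += z1
        return cls(per, (n0, n1))


def _entropy(counts: Sequence[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def info_gain_rank(stats: FeatureStats) -> list[tuple[int, float]]:
    """Elements ranked by information gain of the class given their value.

    Each distinct count value is one category; the gain is computed
    directly from the ordered value-frequency maps.  Descending gain, ties
    broken by ascending element id.
    """
    n0, n1 = stats.class_totals
    if n0 == 0 or n1 == 0:
        raise ValueError("information gain requires both classes present")
    total = n0 + n1
    h_class = _entropy([n0, n1])
    ranked = []
    for e, (c0, c1) in stats.per_element.items():
        values = set(c0) | set(c1)
        h_cond = 0.0
        for v in values:
            a, b = c0.get(v, 0), c1.get(v, 0)
            h_cond += (a + b) / total * _entropy([a, b])
        ranked.append((e, h_class - h_cond))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def symmetrize_scores(score_st: float, score_ts: float) -> float:
    """Arithmetic mean of the two orderings' scores (undirected targets)."""
    return (score_st + score_ts) / 2.0


# -- evaluation ------------------------------------------------------------

@dataclass
class EvalResult:
    auroc: float
    aupr: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """AUROC by midrank Mann-Whitney; AUPR as the step-function area of the
    precision-recall curve, sweeping thresholds from the highest score with
    no interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation requires both classes present")
    ranks = rankdata(scores)
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # PR sweep: tied scores form one threshold group
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = fp = 0
    prev_recall = 0.0
    area = 0.0
    curve: list[tuple[float, float]] = []
    i = 0
    m = len(scores)
    while i < m:
        j = i
        while j < m and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(l_sorted[i:j].sum())
        fp += (j - i) - int(l_sorted[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += precision * (recall - prev_recall)
        curve.append((recall, precision))
        prev_recall = recall
        i = j
    return EvalResult(float(auroc), float(area), curve)


# -- classification --------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Bagged random-subspace ensemble: ``bags`` bootstrap bags, each an
    ensemble of ``subspace_members`` trees trained on a random
    ``subspace_fraction`` of the features."""

    bags: int = 10
    subspace_members: int = 10
    subspace_fraction: float = 0.5
    seed: int = 0


def train_predict(train: PairDataset, test: PairDataset,
                  model: Optional[ModelConfig] = None) -> np.ndarray:
    """Fit the ensemble on the training rows and score the test rows.

    Feature columns are the elements populated in the training set (absent
    elements carry no information for the model and are filtered at zero
    cost).  Each bag is a bootstrap sample of the rows; each member of a bag
    is a decision tree fit on a random subset of the feature columns; scores
    are the mean positive-class probability over all members, in [0, 1].
    """
    from sklearn.tree import DecisionTreeClassifier

    model = model or ModelConfig()
    if train.spec != test.spec:
        raise ValueError("train and test datasets use different universes")
    cols = train.element_ids()
    if not cols:
        raise ValueError("degenerate training set: no populated elements")
    X_train, y_train, _ = train.to_matrix(cols)
    X_test, _, _ = test.to_matrix(cols)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("degenerate training set: single class")
    rng = np.random.default_rng(model.seed)
    n_rows = X_train.shape[0]
    n_feats = X_train.shape[1]
    k = max(1, int(round(model.subspace_fraction * n_feats)))
    Xtr = X_train.tocsc()
    Xte = X_test.tocsc()
    score = np.zeros(X_test.shape[0])
    members = 0
    for _ in range(model.bags):
        bag = rng.integers(0, n_rows, size=n_rows)  # bootstrap rows
        yb = y_train[bag]
        for _ in range(model.subspace_members):
            feats = rng.choice(n_feats, size=k, replace=False)
            feats.sort()
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(0, 2 ** 31)))
            tree.fit(Xtr[:, feats][bag], yb)
            proba = tree.predict_proba(Xte[:, feats])
            if 1 in tree.classes_:
                score += proba[:, list(tree.classes_).index(1)]
            members += 1
    return score / members


def paired_sign_test(wins: int, trials: int) -> float:
    """One-sided sign-test p-value for `wins` successes out of `trials`."""
    return float(binomtest(wins, trials, 0.5, alternative="greater").pvalue)


# -- end-to-end temporal experiment ---------------------------------------

def temporal_experiment(stream: EventStream, num_chunks: int, periods: int,
                        scheme: str = "equal", n: int = 4, mapping=None,
                        prevalence: float = 0.25,
                        model: Optional[ModelConfig] = None,
                        seed: int = 0,
                        num_vertices: Optional[int] = None) -> EvalResult:
    """Sliding-window longitudinal link-prediction experiment.

    The stream is cut into ``num_chunks`` equal-duration chunks.  Training
    features come from chunks [0, T-2) encoded as ``periods`` snapshots,
    training labels from chunk T-2; testing features slide one chunk
    forward (chunks [1, T-1)) with labels from chunk T-1, so training
    labels strictly precede the test label period.  ``periods`` = 1 is the
    temporally unresolved (unirelational) baseline.
    """
    if num_chunks < 3:
        raise ValueError("need at least 3 chunks (features + 2 label chunks)")
    if num_vertices is None:
        num_vertices = stream.max_vertex() + 1
    if mapping is None and n == 4:
        from .isomap import STATIC_CAP, DynamicMapping, build_static_mapping
        spec = UniverseSpec(4, periods, False)
        if (1 << spec.address_bits) <= STATIC_CAP:
            mapping = build_static_mapping(spec)
        else:
            mapping = DynamicMapping(spec)
    B = chunk_boundaries(stream, num_chunks, mode="by-time")
    T = num_chunks

    def one_side(feat_lo: int, feat_hi: int, lab_lo: int, lab_hi: int):
        snap = snapshot_spec(B[feat_lo:feat_hi + 1], periods, scheme)
        feat = snapshot_encode(stream, snap, num_vertices=num_vertices)
        label = from_events(stream, (B[lab_lo], B[lab_hi]),
                            num_vertices=num_vertices)
        pairs = ell2_pairs(feat)
        return build_dataset(feat, label, pairs, n=n, mapping=mapping,
                             feature_window=(B[feat_lo], B[feat_hi]),
                             label_window=(B[lab_lo], B[lab_hi]))

    train = one_side(0, T - 2, T - 2, T - 1)
    test = one_side(1, T - 1, T - 1, T)
    train = undersample(train, prevalence, seed=seed)
    cfg = model or ModelConfig(seed=seed)
    scores = train_predict(train, test, cfg)
    return evaluate(scores, test.labels())
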
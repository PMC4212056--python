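import itertools

import numpy as np
import pytest

from vcp.graphcore import MultiGraph
from vcp.isomap import UniverseSpec
from vcp.linkpred import (EvalResult, FeatureStats, LeakageError, ModelConfig,
                          PairDataset, build_dataset, ell2_pairs, evaluate,
                          info_gain_rank, paired_sign_test, symmetrize_scores,
                          train_predict, undersample)
from vcp.synth import random_multigraph


def bfs_distance2_pairs(graph):
    """Independent oracle: unordered pairs at geodesic distance exactly 2."""
    out = set()
    for src in range(graph.num_vertices):
        dist = {src: 0}
        frontier = [src]
        for depth in (1, 2):
            nxt = []
            for v in frontier:
                for w in graph.neighbors(v):
                    if w not in dist:
                        dist[w] = depth
                        nxt.append(w)
            frontier = nxt
        for v, d in dist.items():
            if d == 2:
                out.add((min(src, v), max(src, v)))
    return sorted(out)


class TestEll2Pairs:
    def test_path(self):
        g = MultiGraph(3)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        assert ell2_pairs(g) == [(0, 2)]

    def test_star(self):
        g = MultiGraph(4)
        for leaf in (1, 2, 3):
            g.add_edge(0, leaf)
        assert ell2_pairs(g) == [(1, 2), (1, 3), (2, 3)]

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_bfs_oracle(self, directed):
        g = random_multigraph(100, 0.03, 1, directed, seed=21)
        assert ell2_pairs(g) == bfs_distance2_pairs(g)


class TestDatasetConstruction:
    def _graphs(self):
        feat = random_multigraph(30, 0.12, 1, False, seed=31)
        label = random_multigraph(30, 0.12, 1, False, seed=32)
        return feat, label

    def test_labels_from_label_graph(self):
        feat, label = self._graphs()
        pairs = ell2_pairs(feat)
        ds = build_dataset(feat, label, pairs, n=3)
        for (s, t, _, lbl) in ds.rows:
            assert lbl == int(label.has_edge(s, t) and not feat.has_edge(s, t))

    def test_features_match_profiles(self):
        from vcp.profiles import vcp3
        feat, label = self._graphs()
        pairs = ell2_pairs(feat)[:5]
        ds = build_dataset(feat, label, pairs, n=3)
        for (s, t, counts, _) in ds.rows:
            assert counts == vcp3(feat, s, t).counts

    def test_leakage_guard(self):
        feat, label = self._graphs()
        with pytest.raises(LeakageError):
            build_dataset(feat, label, [(0, 5)], n=3,
                          feature_window=(0.0, 10.0), label_window=(9.0, 12.0))
        # touching windows are fine: label starts where features end
        build_dataset(feat, label, [(0, 5)], n=3,
                      feature_window=(0.0, 10.0), label_window=(10.0, 12.0))


class TestUndersample:
    def _dataset(self, pos, neg):
        rows = [(i, i + 1, {0: 1}, 1) for i in range(pos)]
        rows += [(i, i + 2, {0: 1}, 0) for i in range(neg)]
        return PairDataset(rows, UniverseSpec(3, 1, False))

    def test_quarter_prevalence(self):
        ds = undersample(self._dataset(100, 900), 0.25, seed=0)
        assert ds.num_positive == 100
        assert len(ds) == 400

    def test_already_at_target_unchanged(self):
        ds = self._dataset(100, 300)
        assert undersample(ds, 0.25, seed=0) is ds

    def test_seed_determinism(self):
        ds = self._dataset(10, 90)
        a = undersample(ds, 0.25, seed=3)
        b = undersample(ds, 0.25, seed=3)
        assert [r[:2] for r in a.rows] == [r[:2] for r in b.rows]

    def test_no_positives_rejected(self):
        rows = [(0, 1, {}, 0)]
        with pytest.raises(ValueError):
            undersample(PairDataset(rows, UniverseSpec(3, 1, False)), 0.25)


class TestInfoGain:
    def _stats(self, rows):
        return FeatureStats.from_dataset(
            PairDataset(rows, UniverseSpec(3, 1, False)))

    def test_identical_distributions_zero_gain(self):
        rows = [(0, 1, {5: 1}, 0), (0, 2, {5: 1}, 1),
                (0, 3, {5: 2}, 0), (0, 4, {5: 2}, 1)]
        ranked = dict(info_gain_rank(self._stats(rows)))
        assert ranked[5] == pytest.approx(0.0)

    def test_perfect_separator_gains_class_entropy(self):
        rows = [(0, 1, {7: 1}, 1), (0, 2, {7: 1}, 1),
                (0, 3, {7: 3}, 0), (0, 4, {7: 3}, 0)]
        ranked = dict(info_gain_rank(self._stats(rows)))
        assert ranked[7] == pytest.approx(1.0)  # H(class) = 1 bit

    def test_matches_brute_force_entropy(self):
        # 8-row dataset, two elements, hand-computable
        rows = [(0, 1, {1: 1, 2: 4}, 1), (0, 2, {1: 1}, 1),
                (0, 3, {2: 4}, 1), (0, 4, {}, 1),
                (0, 5, {1: 1}, 0), (0, 6, {}, 0),
                (0, 7, {}, 0), (0, 8, {}, 0)]
        ranked = dict(info_gain_rank(self._stats(rows)))

        def H(*cs):
            tot = sum(cs)
            return -sum(c / tot * np.log2(c / tot) for c in cs if c)

        # element 1: value 1 -> (pos 2, neg 1); value 0 -> (pos 2, neg 3)
        expect1 = H(4, 4) - (3 / 8) * H(2, 1) - (5 / 8) * H(2, 3)
        # element 2: value 4 -> (pos 2, neg 0); value 0 -> (pos 2, neg 4)
        expect2 = H(4, 4) - (2 / 8) * H(2, 0) - (6 / 8) * H(2, 4)
        assert ranked[1] == pytest.approx(expect1)
        assert ranked[2] == pytest.approx(expect2)

    def test_zero_values_complete_totals(self):
        rows = [(0, 1, {3: 2}, 1), (0, 2, {}, 0), (0, 3, {}, 0)]
        stats = FeatureStats.from_dataset(
            PairDataset(rows, UniverseSpec(3, 1, False)))
        c0, c1 = stats.per_element[3]
        assert sum(c0.values()) + sum(c1.values()) == 3


class TestSymmetrize:
    def test_mean(self):
        assert symmetrize_scores(0.2, 0.4) == pytest.approx(0.3)
        assert symmetrize_scores(0.7, 0.7) == 0.7
        assert symmetrize_scores(0.1, 0.9) == symmetrize_scores(0.9, 0.1)


class TestEvaluate:
    def test_perfect_separation(self):
        r = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auroc == 1.0 and r.aupr == 1.0

    def test_all_tied_conventions(self):
        r = evaluate([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert r.auroc == pytest.approx(0.5)
        assert r.aupr == pytest.approx(0.2)  # prevalence

    def test_hand_example_matches_sweep_oracle(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 0, 1, 1, 0, 0]
        r = evaluate(scores, labels)
        # threshold sweep by hand: precisions 1, 1/2, 2/3, 3/4 at recalls
        # 1/3, 1/3, 2/3, 1
        expect_aupr = (1 / 3) * 1 + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 4)
        assert r.aupr == pytest.approx(expect_aupr)
        assert r.auroc == pytest.approx(7 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [1, 1])

    def test_matches_sklearn_on_random_sets(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(5, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=m)
            labels = rng.integers(0, 2, size=m)
            if labels.min() == labels.max():
                continue
            r = evaluate(scores, labels)
            assert r.auroc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9)

    def test_aupr_matches_brute_force_sweep(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = int(rng.integers(5, 30))
            scores = rng.choice([0.2, 0.4, 0.6, 0.8], size=m)
            labels = rng.integers(0, 2, size=m)
            if labels.min() == labels.max():
                continue
            r = evaluate(scores, labels)
            # brute force: every distinct score as a threshold, descending
            npos = labels.sum()
            area = 0.0
            prev_rec = 0.0
            for th in sorted(set(scores), reverse=True):
                sel = scores >= th
                tp = int((labels[sel] == 1).sum())
                prec = tp / sel.sum()
                rec = tp / npos
                area += prec * (rec - prev_rec)
                prev_rec = rec
            assert r.aupr == pytest.approx(area, abs=1e-9)


def _synthetic_datasets(seed, separable=True, n_rows=200):
    """Sparse count features where elements 0/1 carry the class signal."""
    rng = np.random.default_rng(seed)
    spec = UniverseSpec(4, 1, False)

    def make(n):
        rows = []
        for i in range(n):
            lbl = int(rng.random() < 0.4)
            key = lbl if separable else int(rng.random() < 0.5)
            counts = {key: int(rng.integers(3, 6)),
                      2 + int(rng.integers(0, 5)): 1}
            rows.append((i, n + i, counts, lbl))
        return PairDataset(rows, spec)

    return make(n_rows), make(n_rows)


class TestTrainPredict:
    def test_separable_features_high_auroc(self):
        for seed in range(5):
            train, test = _synthetic_datasets(seed)
            scores = train_predict(train, test, ModelConfig(seed=seed))
            assert evaluate(scores, test.labels()).auroc >= 0.95

    def test_permuted_labels_near_chance(self):
        aurocs = []
        for seed in range(5):
            train, test = _synthetic_datasets(seed, n_rows=300)
            rng = np.random.default_rng(10_000 + seed)  # independent of data
            rows = [(s, t, c, int(l)) for (s, t, c, _), l in
                    zip(train.rows, rng.permutation(train.labels()))]
            train = PairDataset(rows, train.spec)
            scores = train_predict(train, test, ModelConfig(seed=seed))
            aurocs.append(evaluate(scores, test.labels()).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_degenerate_training_rejected(self):
        spec = UniverseSpec(4, 1, False)
        rows = [(0, 1, {0: 1}, 1), (0, 2, {0: 2}, 1)]
        ds = PairDataset(rows, spec)
        with pytest.raises(ValueError):
            train_predict(ds, ds)

    def test_seeded_reproducibility(self):
        train, test = _synthetic_datasets(7)
        a = train_predict(train, test, ModelConfig(seed=11))
        b = train_predict(train, test, ModelConfig(seed=11))
        assert np.array_equal(a, b)


class TestSignTest:
    def test_extreme_and_null(self):
        assert paired_sign_test(10, 10) == pytest.approx(0.5 ** 10)
        assert paired_sign_test(5, 10) > 0.5
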
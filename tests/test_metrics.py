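"""Metric implementations against brute-force and established oracles."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from sece.io import CoordinateTable, DomainLabeling
from sece.metrics import ContingencyTable, acc, ari, asw, lisi


def _brute_ari(a, b):
    """Pair-enumeration adjusted Rand index."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and not sb
            n01 += (not sa) and sb
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


class TestARI:
    def test_identical_partitions(self, labeling):
        assert ari(labeling, labeling) == 1.0

    def test_relabel_invariance(self, rng):
        t = rng.integers(0, 4, size=50)
        perm = rng.permutation(4)
        assert np.isclose(ari(t, perm[t]), 1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=20)
            b = rng.integers(0, 3, size=20)
            assert np.isclose(ari(a, b), _brute_ari(a, b), atol=1e-12)

    def test_matches_sklearn_on_many_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, int(rng.integers(2, 6)), size=n)
            b = rng.integers(0, int(rng.integers(2, 6)), size=n)
            assert np.isclose(ari(a, b), adjusted_rand_score(a, b), atol=1e-10)

    def test_contingency_margins(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 5, size=30)
        ct = ContingencyTable.from_labels(a, b)
        assert ct.n_ij.sum() == ct.a_i.sum() == ct.b_j.sum() == ct.N == 30

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestACC:
    def test_bijective_relabel_gives_one(self, rng):
        t = rng.integers(0, 5, size=60)
        perm = rng.permutation(5)
        assert acc(t, perm[t]) == 1.0

    def test_constant_predictor_balanced(self):
        t = np.repeat(np.arange(4), 10)
        p = np.zeros(40, dtype=int)
        assert np.isclose(acc(t, p), 0.25)

    def test_matches_exhaustive_bijection_search(self, rng):
        for _ in range(10):
            t = rng.integers(0, 4, size=30)
            p = rng.integers(0, 4, size=30)
            best = max(np.mean(t == np.array(mapping)[p])
                       for mapping in itertools.permutations(range(4)))
            assert np.isclose(acc(t, p), best, atol=1e-12)

    def test_rectangular_label_sets(self, rng):
        t = rng.integers(0, 3, size=40)
        p = rng.integers(0, 5, size=40)
        best = 0.0
        for mapping in itertools.permutations(range(5), 5):
            # predicted label j maps to true label mapping[j]; only 0..2 can match
            best = max(best, np.mean(np.array(mapping)[p] == t))
        assert np.isclose(acc(t, p), best, atol=1e-12)

    def test_constant_predictor_achieves_largest_class(self, rng):
        # a constant prediction is optimally matched to the largest truth class
        for _ in range(20):
            t = rng.integers(0, 4, size=50)
            p = np.full(50, 2)
            assert np.isclose(acc(t, p), np.bincount(t).max() / 50, atol=1e-12)


def _brute_silhouette(x, labels):
    n = len(x)
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    vals = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals[i] = 0.0
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        vals[i] = (b - a) / max(a, b)
    return vals.mean()


class TestASW:
    def test_separated_clusters_near_one(self, rng):
        x = np.vstack([rng.normal(0, 1, size=(30, 3)),
                       rng.normal(100, 1, size=(30, 3))])
        labels = np.repeat([0, 1], 30)
        assert asw(x, labels) > 0.95

    def test_random_labels_near_zero(self, rng):
        x = rng.normal(size=(200, 3))
        vals = [asw(x, np.random.default_rng(s).integers(0, 2, size=200))
                for s in range(5)]
        assert max(abs(v) for v in vals) < 0.05

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(40, 4))
        labels = rng.integers(0, 3, size=40)
        assert np.isclose(asw(x, labels), _brute_silhouette(x, labels), atol=1e-12)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            asw(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))


class TestLISI:
    def test_pure_neighborhood(self):
        y = np.column_stack([np.arange(20.0), np.zeros(20)])
        labels = np.repeat([0, 1], 10)
        vals_raw, _ = lisi(y, labels, neighborhood_size=5, normalized=False)
        assert vals_raw[0] == 1.0  # deep inside a single-label region
        vals_norm, _ = lisi(y, labels, neighborhood_size=5, normalized=True)
        assert np.isclose(vals_norm[0], 0.5)

    def test_maximal_mixing(self):
        # alternating labels along a line: any even-size neighborhood is split 50/50
        y = np.column_stack([np.arange(40.0), np.zeros(40)])
        labels = np.tile([0, 1], 20)
        vals, mean = lisi(y, labels, neighborhood_size=2, normalized=False)
        assert np.allclose(vals, 2.0)
        _, mean_norm = lisi(y, labels, neighborhood_size=2, normalized=True)
        assert np.isclose(mean_norm, 1.0)

    def test_matches_bruteforce_simpson(self, rng):
        y = rng.normal(size=(50, 2))
        labels = rng.integers(0, 3, size=50)
        k = 10
        vals, mean = lisi(y, labels, neighborhood_size=k, normalized=False)
        for i in range(50):
            d = np.linalg.norm(y - y[i], axis=1)
            neigh = np.argsort(d, kind="stable")[:k]
            p = np.bincount(labels[neigh], minlength=3) / k
            assert np.isclose(vals[i], 1.0 / np.sum(p ** 2), atol=1e-12)
        assert np.isclose(mean, vals.mean())

    def test_range_bounds(self, rng):
        y = rng.normal(size=(80, 2))
        labels = rng.integers(0, 4, size=80)
        vals, _ = lisi(y, labels, neighborhood_size=15, normalized=False)
        assert np.all(vals >= 1.0 - 1e-12) and np.all(vals <= 4.0 + 1e-12)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            lisi(rng.normal(size=(10, 2)), np.zeros(10, dtype=int), neighborhood_size=10)


def test_metrics_invariant_to_prediction_relabeling(rng, small_fixture):
    _, coords, truth = small_fixture
    pred = rng.integers(0, 3, size=len(truth.labels))
    perm = rng.permutation(3)
    assert np.isclose(ari(truth.labels, pred), ari(truth.labels, perm[pred]), atol=1e-12)
    assert np.isclose(acc(truth.labels, pred), acc(truth.labels, perm[pred]), atol=1e-12)
    _, m1 = lisi(coords, pred, neighborhood_size=10)
    _, m2 = lisi(coords, perm[pred], neighborhood_size=10)
    assert np.isclose(m1, m2, atol=1e-12)
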
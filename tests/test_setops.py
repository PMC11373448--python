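"""Venn tallies, Jaccard similarity and clustering order."""

import itertools
import random

import numpy as np
import pytest

from vcfcompare import (
    SimilarityMatrix,
    cluster_order,
    intersection_all,
    jaccard,
    jaccard_matrix,
    venn_tally,
)
from vcfcompare.errors import ArityError, UndefinedScoreError
from conftest import random_keys


def brute_force_tally(sets):
    """Independent oracle: classify every union member by direct lookup."""
    names = list(sets)
    counts = {m: 0 for m in range(1, 2 ** len(names))}
    for v in set().union(*(set(s) for s in sets.values())):
        mask = sum(1 << i for i, n in enumerate(names) if v in sets[n])
        counts[mask] += 1
    return counts


class TestVennTally:
    def test_disjoint_two_sets(self):
        t = venn_tally({"A": {1, 2, 3}, "B": {4, 5}})
        assert t.counts == {0b01: 3, 0b10: 2, 0b11: 0}
        assert t.total == 5

    def test_three_set_enumeration(self):
        t = venn_tally({"A": {1, 2}, "B": {2, 3}, "C": {2}})
        assert t.counts[0b111] == 1
        assert t.counts[0b001] == 1
        assert t.counts[0b010] == 1
        assert sum(t.counts.values()) == 3
        assert all(
            c == 0 for m, c in t.counts.items() if m not in (0b111, 0b001, 0b010)
        )

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_random_sets_match_brute_force_oracle(self, k, rng):
        sets = {
            f"s{i}": set(random_keys(rng, rng.randrange(10, 100)))
            for i in range(k)
        }
        t = venn_tally(sets)
        assert t.counts == brute_force_tally(sets)
        assert t.total == len(set().union(*sets.values()))
        assert abs(sum(t.percentages.values()) - 1.0) < 1e-9

    @pytest.mark.parametrize("k", [1, 7])
    def test_arity_outside_2_to_6_rejected(self, k):
        with pytest.raises(ArityError):
            venn_tally({f"s{i}": {1} for i in range(k)})

    def test_pattern_labels_follow_set_order(self):
        t = venn_tally({"A": {1}, "B": {1}})
        assert t.pattern_label(0b11) == "A & B"


class TestIntersection:
    def test_all_sets_pattern_consistency(self, rng):
        sets = {f"s{i}": set(random_keys(rng, 40)) for i in range(3)}
        t = venn_tally(sets)
        common = intersection_all(sets)
        assert t.counts[0b111] == len(common)

    def test_any_empty_set_empties_intersection(self):
        assert intersection_all({"A": {1, 2}, "B": set()}) == set()

    def test_identical_sets(self):
        assert intersection_all({"A": {1, 2}, "B": {1, 2}}) == {1, 2}


class TestJaccard:
    def test_identity_disjoint_and_half(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard({1}, {2}) == 0.0
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_symmetry_random(self, rng):
        a, b = set(random_keys(rng, 30)), set(random_keys(rng, 30))
        assert jaccard(a, b) == jaccard(b, a)

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedScoreError):
            jaccard(set(), set())

    def test_matrix_matches_pairwise_calls(self, rng):
        sets = {f"s{i}": set(random_keys(rng, 25)) for i in range(4)}
        m = jaccard_matrix(sets)
        names = list(sets)
        for i, j in itertools.combinations(range(4), 2):
            assert m.values[i, j] == jaccard(sets[names[i]], sets[names[j]])
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_empty_set_named_in_error(self):
        with pytest.raises(UndefinedScoreError, match="bad"):
            jaccard_matrix({"ok": {1}, "bad": set()})


def reference_average_linkage(dist):
    """Tiny brute-force agglomerative average linkage (independent of scipy).

    Returns merge heights in order, using unweighted pair-group averaging
    over the original observations (UPGMA), like scipy's 'average'.
    """
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    next_id = len(dist)
    d = {
        frozenset((i, j)): dist[i][j]
        for i in range(len(dist))
        for j in range(i + 1, len(dist))
    }
    while len(clusters) > 1:
        pair = min(d, key=lambda p: (d[p], sorted(p)))
        i, j = sorted(pair)
        heights.append(d[pair])
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        for k in clusters:
            members = clusters[k]
            avg = sum(
                dist[a][b] for a in merged for b in members
            ) / (len(merged) * len(members))
            d[frozenset((next_id, k))] = avg
        d = {p: v for p, v in d.items() if i not in p and j not in p}
        clusters[next_id] = merged
        next_id += 1
    return heights


class TestClusterOrder:
    def test_two_sets_keep_input_order(self):
        m = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert cluster_order(m).leaf_order == [0, 1]

    def test_most_similar_pair_merges_first(self):
        j = np.array([
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.1],
            [0.1, 0.1, 1.0],
        ])
        res = cluster_order(SimilarityMatrix(["a", "b", "c"], j))
        assert sorted(res.linkage[0, :2].astype(int).tolist()) == [0, 1]

    def test_merge_heights_match_reference_and_are_monotone(self, rng):
        k = 6
        vals = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                vals[i, j] = vals[j, i] = rng.random()
        m = SimilarityMatrix([f"s{i}" for i in range(k)], vals)
        res = cluster_order(m)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
        dist = (1.0 - vals).tolist()
        expected = reference_average_linkage(dist)
        assert np.allclose(sorted(heights), sorted(expected))

    @staticmethod
    def _merge_clusters(labels, linkage):
        """Frozensets of member names formed at each merge, order-free."""
        clusters = {i: frozenset([n]) for i, n in enumerate(labels)}
        formed = set()
        for row, (i, j, _, _) in enumerate(linkage):
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[len(labels) + row] = merged
            formed.add(merged)
        return formed

    def test_merge_topology_invariant_under_input_permutation(self, rng):
        k = 5
        vals = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                vals[i, j] = vals[j, i] = rng.random()
        labels = [f"s{i}" for i in range(k)]
        base = cluster_order(SimilarityMatrix(labels, vals))
        perm = list(range(k))
        rng.shuffle(perm)
        pv = vals[np.ix_(perm, perm)]
        plabels = [labels[i] for i in perm]
        res = cluster_order(SimilarityMatrix(plabels, pv))
        assert self._merge_clusters(labels, base.linkage) == self._merge_clusters(
            plabels, res.linkage
        )
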
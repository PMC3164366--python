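"""Overlap-distance construction and complete-linkage agreement."""

import itertools

import numpy as np
import pytest

from listcomp import (
    ContractError,
    OverlapDistanceMatrix,
    build_distance_matrix,
    complete_linkage,
)


def naive_complete_linkage(d: np.ndarray):
    """Reference agglomerator: O(C^3) textbook complete linkage.

    Returns the merge history as (frozenset of leaf ids, height) records.
    """
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(len(d))}
    history = []
    next_id = len(d)
    dist = {(i, j): d[i, j] for i in range(len(d)) for j in range(i + 1, len(d))}
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        history.append((merged, h))
        del clusters[i], clusters[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k in clusters:
            dik = d[np.ix_(sorted(clusters[k]), sorted(merged))].max()
            dist[(min(k, next_id), max(k, next_id))] = dik
        clusters[next_id] = merged
        next_id += 1
    return history


def scipy_history(labels, linkage):
    """The same merge-history representation from a scipy linkage matrix."""
    n = len(labels)
    members = {i: frozenset([i]) for i in range(n)}
    history = []
    for row_idx, (a, b, h, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        history.append((merged, h))
    return history


def random_distance_matrix(c, rng):
    """Random symmetric distances with min off-diagonal 0 — the image of the
    max-overlap-minus-k construction."""
    d = rng.uniform(1.0, 100.0, size=(c, c))
    d = (d + d.T) / 2
    off = ~np.eye(c, dtype=bool)
    d[off] -= d[off].min()
    np.fill_diagonal(d, 0.0)
    return d


class TestDistanceMatrix:
    def test_three_condition_arithmetic(self):
        dist = build_distance_matrix(
            ["A", "B", "C"], {("A", "B"): 10, ("A", "C"): 4, ("B", "C"): 0}
        )
        d = dist.d_matrix
        idx = {lab: i for i, lab in enumerate(dist.condition_labels)}
        assert d[idx["A"], idx["B"]] == 0
        assert d[idx["A"], idx["C"]] == 6
        assert d[idx["B"], idx["C"]] == 10

    def test_equal_overlaps_give_zero_distances(self):
        dist = build_distance_matrix(
            ["A", "B", "C"], {("A", "B"): 7, ("A", "C"): 7, ("B", "C"): 7}
        )
        off = ~np.eye(3, dtype=bool)
        assert np.all(dist.d_matrix[off] == 0)

    def test_distances_symmetric_non_negative(self):
        rng = np.random.default_rng(0)
        labels = [f"c{i}" for i in range(5)]
        pairs = {
            (a, b): int(rng.integers(0, 50))
            for a, b in itertools.combinations(labels, 2)
        }
        d = build_distance_matrix(labels, pairs).d_matrix
        assert np.allclose(d, d.T)
        assert np.all(d >= 0)

    def test_missing_pair_reported(self):
        with pytest.raises(ContractError, match="missing"):
            build_distance_matrix(["A", "B", "C"], {("A", "B"): 1})


class TestCompleteLinkage:
    def test_three_leaf_hand_example(self):
        dist = build_distance_matrix(
            ["A", "B", "C"], {("A", "B"): 10, ("A", "C"): 4, ("B", "C"): 0}
        )
        tree = complete_linkage(dist)
        # first merge (A, B) at height 0; then C joins at max(6, 10) = 10
        assert tree.merge_heights[0] == 0
        assert tree.merge_heights[1] == 10
        hist = scipy_history(tree.labels, tree.linkage)
        idx = {lab: i for i, lab in enumerate(tree.labels)}
        assert hist[0][0] == frozenset([idx["A"], idx["B"]])

    def test_two_conditions_single_merge(self):
        dist = build_distance_matrix(["A", "B"], {("A", "B"): 3})
        tree = complete_linkage(dist)
        assert len(tree.merge_heights) == 1
        assert tree.merge_heights[0] == 0  # the unique pair is the max pair

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            c = int(rng.integers(3, 9))
            tree = complete_linkage(_wrap(random_distance_matrix(c, rng)))
            assert np.all(np.diff(tree.merge_heights) >= -1e-12)

    def test_agrees_with_naive_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = int(rng.integers(3, 11))
            d = random_distance_matrix(c, rng)
            tree = complete_linkage(_wrap(d))
            ours = scipy_history(tree.labels, tree.linkage)
            ref = naive_complete_linkage(d)
            for (set_a, h_a), (set_b, h_b) in zip(ours, ref):
                assert set_a == set_b
                assert h_a == pytest.approx(h_b, abs=1e-9)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        c = 7
        d = random_distance_matrix(c, rng)
        labels = [f"c{i}" for i in range(c)]
        perm = rng.permutation(c)
        d2 = d[np.ix_(perm, perm)]
        t1 = complete_linkage(_wrap(d, labels))
        t2 = complete_linkage(_wrap(d2, [labels[i] for i in perm]))
        h1 = {s: h for s, h in _label_history(t1)}
        h2 = {s: h for s, h in _label_history(t2)}
        assert h1.keys() == h2.keys()
        for key in h1:
            assert h1[key] == pytest.approx(h2[key], abs=1e-9)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(4)
        tree = complete_linkage(_wrap(random_distance_matrix(6, rng)))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(tree.labels)

    def test_flat_cut_recovers_two_blocks(self):
        # two tight groups far apart: the 2-cluster cut is the bipartition
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        k = {}
        for x, y in itertools.combinations(labels, 2):
            k[(x, y)] = 90 if x[0] == y[0] else 2
        tree = complete_linkage(build_distance_matrix(labels, k))
        cut = tree.cut(2)
        groups = {}
        for lab, cid in cut.items():
            groups.setdefault(cid, set()).add(lab)
        assert sorted(map(sorted, groups.values())) == [
            ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        ]


def _wrap(d: np.ndarray, labels=None) -> OverlapDistanceMatrix:
    """Build an OverlapDistanceMatrix whose derived distances equal ``d``."""
    c = len(d)
    labels = labels or [f"c{i}" for i in range(c)]
    off = ~np.eye(c, dtype=bool)
    k = d[off].max() - d
    np.fill_diagonal(k, 0.0)
    out = OverlapDistanceMatrix(condition_labels=list(labels), k_matrix=k)
    assert np.allclose(out.d_matrix, d)
    return out


def _label_history(tree):
    n = len(tree.labels)
    members = {i: frozenset([tree.labels[i]]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _) in enumerate(tree.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append((merged, h))
    return out
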
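"""The marching list comparison: traces, verdicts, symmetry, determinism."""

import numpy as np
import pytest

from listcomp import (
    ContractError,
    FoldChangeTable,
    compare_directional,
    compare_lists,
    make_ranked_list,
    make_related_tables,
    rank_genes,
    shuffle_unconstrained,
    venn_counts,
)
from listcomp.core import NOT_SIGNIFICANT, SIGNIFICANT


class TestCompareLists:
    def test_identical_lists_select_everything(self):
        # a directional list covers part of the universe, as after ranking
        la = make_ranked_list(600, seed=0, n_ranked=500)
        res = compare_lists(la, la, step=100)
        assert res.verdict == SIGNIFICANT
        assert res.selected_depth == 500
        assert sorted(res.common_genes) == sorted(la.genes)

    def test_self_comparison_total_for_any_step(self):
        la = make_ranked_list(260, seed=1, n_ranked=130)
        for step in (1, 7, 50, 130, 1000):
            res = compare_lists(la, la, step=step, alpha=0.01)
            assert res.selected_depth == 130
            assert len(res.common_genes) == 130

    def test_unrelated_lists_usually_not_significant(self):
        la = make_ranked_list(2000, seed=2)
        hits = sum(
            compare_lists(la, shuffle_unconstrained(la, seed=s), step=100).verdict
            == SIGNIFICANT
            for s in range(40)
        )
        assert hits <= 6  # ~alpha-level false positive rate

    def test_symmetric_in_arguments(self):
        la = make_ranked_list(800, seed=3)
        lb = shuffle_unconstrained(la, seed=99)
        r1 = compare_lists(la, lb, step=50)
        r2 = compare_lists(lb, la, step=50)
        assert r1.selected_depth == r2.selected_depth
        assert r1.verdict == r2.verdict
        assert r1.common_genes == r2.common_genes

    def test_trace_overlap_counts_monotone(self):
        la = make_ranked_list(1000, seed=4)
        lb = shuffle_unconstrained(la, seed=5)
        res = compare_lists(la, lb, step=100)
        ks = [rec.k for rec in res.trace]
        ms = [rec.m for rec in res.trace]
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        assert all(k <= m for k, m in zip(ks, ms))

    def test_first_step_has_no_increment_test(self):
        la = make_ranked_list(400, seed=6, n_ranked=300)
        res = compare_lists(la, la, step=100)
        assert res.trace[0].increment_p is None
        assert all(rec.increment_p is not None for rec in res.trace[1:])

    def test_oversized_step_collapses_to_single_evaluation(self):
        la = make_ranked_list(80, seed=7)
        res = compare_lists(la, la, step=500)
        assert [rec.m for rec in res.trace] == [80]

    def test_partial_final_step(self):
        la = make_ranked_list(250, seed=8)
        res = compare_lists(la, la, step=100)
        assert [rec.m for rec in res.trace] == [100, 200, 250]

    def test_mismatched_universes_rejected(self):
        la = make_ranked_list(100, seed=9)
        lb = make_ranked_list(200, seed=9)
        with pytest.raises(ContractError):
            compare_lists(la, lb)

    def test_mismatched_directions_rejected(self):
        la = make_ranked_list(100, seed=10, direction="up")
        lb = make_ranked_list(100, seed=10, direction="down")
        with pytest.raises(ContractError):
            compare_lists(la, lb)

    def test_non_positive_step_rejected(self):
        la = make_ranked_list(100, seed=11)
        with pytest.raises(ContractError):
            compare_lists(la, la, step=0)

    def test_deterministic_repeatable(self):
        la = make_ranked_list(600, seed=12)
        lb = shuffle_unconstrained(la, seed=13)
        r1 = compare_lists(la, lb, step=50)
        r2 = compare_lists(la, lb, step=50)
        assert r1 == r2


class TestCompareDirectional:
    def test_self_comparison_recovers_all_nonzero_genes(self):
        fc, _, _ = make_related_tables(400, 0.5, 2.0, 0.3, seed=0)
        up, down = compare_directional(fc, fc, step=50)
        signature = set(up.common_genes) | set(down.common_genes)
        nonzero = {g for g, v in zip(fc.genes, fc.fold_change) if v != 0}
        assert signature == nonzero

    def test_sign_flip_kills_both_directions(self):
        fc, _, _ = make_related_tables(600, 0.5, 2.0, 0.3, seed=1)
        flipped = FoldChangeTable(genes=fc.genes.copy(), fold_change=-fc.fold_change)
        up, down = compare_directional(fc, flipped, step=100)
        assert up.verdict == NOT_SIGNIFICANT
        assert down.verdict == NOT_SIGNIFICANT
        assert up.common_genes == [] and down.common_genes == []

    def test_planted_signature_recovered_within_tolerance(self):
        sizes = []
        for seed in range(10):
            fa, fb, planted = make_related_tables(5000, 0.3, 2.0, 0.5, seed=seed)
            up, down = compare_directional(fa, fb)
            sizes.append(len(up.common_genes) + len(down.common_genes))
        target = 0.3 * 5000
        assert abs(np.median(sizes) - target) / target < 0.15

    def test_restricted_to_shared_universe(self):
        fa, _, _ = make_related_tables(200, 0.5, 2.0, 0.2, seed=3)
        # drop half the genes from b: N must shrink to the shared universe
        keep = list(fa.genes[:100])
        fb = fa.restrict(keep)
        up, down = compare_directional(fa, fb, step=20)
        for res in (up, down):
            assert res.universe_size == 100

    def test_disjoint_universes_rejected(self):
        fa = FoldChangeTable(genes=np.array(["A"], dtype=object),
                             fold_change=np.array([1.0]))
        fb = FoldChangeTable(genes=np.array(["B"], dtype=object),
                             fold_change=np.array([1.0]))
        with pytest.raises(ContractError):
            compare_directional(fa, fb)


class TestVennCounts:
    def test_identical_lists_have_no_private_genes(self):
        fc, _, _ = make_related_tables(300, 1.0, 2.0, 0.0, seed=4)
        up, down = compare_directional(fc, fc, step=50)
        venn = venn_counts(up, down)
        assert venn.up.a_only == venn.up.b_only == 0
        assert venn.up.common == len(up.common_genes)

    def test_private_counts_are_depth_minus_overlap(self):
        fa, fb, _ = make_related_tables(2000, 0.3, 2.0, 0.5, seed=5)
        up, down = compare_directional(fa, fb)
        venn = venn_counts(up, down)
        assert venn.up.a_only == up.selected_depth - up.overlap_size
        assert venn.up.b_only == venn.up.a_only

    def test_no_venn_for_non_significant_direction(self):
        fc, _, _ = make_related_tables(600, 0.5, 2.0, 0.3, seed=6)
        flipped = FoldChangeTable(genes=fc.genes.copy(), fold_change=-fc.fold_change)
        up, down = compare_directional(fc, flipped, step=100)
        venn = venn_counts(up, down)
        assert venn.up is None and venn.down is None
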
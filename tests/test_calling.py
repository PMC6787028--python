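"""Window testing, p-value combination, FDR, peak merging, truth recovery."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meripeak.calling import (
    Peak,
    bh_adjust,
    call_windows,
    combine_replicates,
    evaluate_against_truth,
    fisher_window_test,
    merge_windows,
)
from meripeak.simulate import SimulationTruth, TruthPeak
from meripeak.windows import LibraryTotals, build_windows

from conftest import make_model


def hypergeom_tail_exact(k, K, m, M):
    """Upper-tail p by exact integer enumeration of all 2x2 tables with the
    observed margins: P(window IP count >= k)."""
    n = k + m
    denom = math.comb(K + M, n)
    num = sum(math.comb(K, i) * math.comb(M, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(num, denom))


class TestFisherWindowTest:
    def test_empty_window_gives_one(self):
        assert fisher_window_test(0, 100, 0, 100) == 1.0

    def test_enumeration_value_small_table(self):
        # all-IP window: only 1 of C(6,3)=20 tables is as extreme
        assert fisher_window_test(3, 3, 0, 3) == pytest.approx(0.05, abs=1e-12)

    def test_equal_proportions_not_enriched(self):
        assert fisher_window_test(5, 100, 5, 100) > 0.5

    def test_empty_library_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_window_test(0, 0, 3, 10) == 1.0

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_test(5, 3, 0, 10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_exact_enumeration_and_scipy(self, data):
        K = data.draw(st.integers(1, 30))
        M = data.draw(st.integers(1, 30))
        k = data.draw(st.integers(0, K))
        m = data.draw(st.integers(0, M))
        p = fisher_window_test(k, K, m, M)
        assert p == pytest.approx(hypergeom_tail_exact(k, K, m, M), abs=1e-9)
        _, p_sp = stats.fisher_exact([[k, K - k], [m, M - m]], alternative="greater")
        assert p == pytest.approx(p_sp, abs=1e-9)


class TestCombineReplicates:
    def test_single_p_identity(self):
        for p in (0.001, 0.05, 0.5, 1.0):
            assert combine_replicates([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones_combine_to_one(self):
        assert combine_replicates([1.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_four_df(self):
        # chi2 sf with 4 df has closed form e^{-x/2} (1 + x/2)
        x = -2 * (math.log(0.05) + math.log(0.05))
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert combine_replicates([0.05, 0.05]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0175, abs=2e-4)

    def test_agrees_with_scipy_combine_pvalues(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ps = rng.uniform(1e-6, 1, size=rng.integers(1, 5)).tolist()
            expected = stats.combine_pvalues(ps, method="fisher").pvalue
            assert combine_replicates(ps) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_and_monotone(self):
        assert combine_replicates([0.01, 0.3]) == combine_replicates([0.3, 0.01])
        base = combine_replicates([0.05, 0.2])
        assert combine_replicates([0.01, 0.2]) < base
        assert combine_replicates([0.05, 0.1]) < base

    def test_zero_clamped(self):
        assert 0.0 <= combine_replicates([0.0, 0.5]) < 1e-100


def bh_bruteforce(p):
    """Textbook step-up: q(i) = min over j >= i of min(1, m p(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBHAdjust:
    def test_singleton_unchanged(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_worked_example(self):
        got = bh_adjust([0.001, 0.01, 0.02, 0.04, 0.2])
        assert got == pytest.approx([0.005, 0.025, 1 / 30, 0.05, 0.2], abs=1e-9)

    def test_constant_vector_fixed_point(self):
        assert bh_adjust([0.03] * 7) == pytest.approx([0.03] * 7)

    def test_empty_vector(self):
        assert len(bh_adjust([])) == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_bruteforce(p), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))


def counted_windows(counts, gene="g", width=25):
    """Windows for one gene with given list of {(sample, rep): count}."""
    m = make_model(gene, "chr1", "+", [(0, width * len(counts))])
    ws = build_windows(m, width)
    for w, c in zip(ws, counts):
        w.counts = dict(c)
    return ws


class TestCallWindows:
    def test_singleton_significant_iff_p_below_alpha(self):
        ws = counted_windows([{("IP", 1): 50, ("input", 1): 5}])
        totals = LibraryTotals({("IP", 1): 1000, ("input", 1): 1000})
        tests = call_windows(ws, totals, alpha=0.05)
        assert len(tests) == 1
        t = tests[0]
        assert t.q == pytest.approx(t.p_combined)  # BH of a singleton
        assert t.significant == (t.p_combined < 0.05)
        assert t.significant

    def test_flat_replicates_not_significant(self):
        ws = counted_windows([{("IP", 1): 0, ("input", 1): 0, ("IP", 2): 0, ("input", 2): 0}])
        totals = LibraryTotals({("IP", 1): 100, ("input", 1): 100, ("IP", 2): 100, ("input", 2): 100})
        t = call_windows(ws, totals)[0]
        assert t.p_replicates == [1.0, 1.0]
        assert t.q == pytest.approx(1.0)
        assert not t.significant

    def test_unpaired_replicates_rejected(self):
        ws = counted_windows([{("IP", 1): 5}])
        totals = LibraryTotals({("IP", 1): 100, ("input", 2): 100})
        with pytest.raises(ValueError, match="paired"):
            call_windows(ws, totals)

    def test_adjust_then_combine_mode_runs(self):
        ws = counted_windows(
            [{("IP", 1): 40, ("input", 1): 2, ("IP", 2): 35, ("input", 2): 3},
             {("IP", 1): 4, ("input", 1): 5, ("IP", 2): 6, ("input", 2): 5}]
        )
        totals = LibraryTotals(
            {("IP", 1): 1000, ("input", 1): 1000, ("IP", 2): 1000, ("input", 2): 1000}
        )
        both = {
            order: call_windows(ws, totals, order=order)
            for order in ("combine-then-adjust", "adjust-then-combine")
        }
        for tests in both.values():
            assert tests[0].significant and not tests[1].significant


def make_flag_tests(flags, gene="g", q=0.01):
    """WindowTest list with the given significance pattern (one gene)."""
    ws = counted_windows([{("IP", 1): 10, ("input", 1): 1} for _ in flags], gene=gene)
    totals = LibraryTotals({("IP", 1): 1000, ("input", 1): 1000})
    tests = call_windows(ws, totals)
    for t, f in zip(tests, flags):
        t.significant = bool(f)
        t.q = q if f else 1.0
    return tests


class TestMergeWindows:
    def test_four_window_run_is_kept_at_boundary(self):
        peaks = merge_windows(make_flag_tests([1, 1, 1, 1]))
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.t_start, p.t_end, p.n_windows, p.length) == (0, 100, 4, 100)

    def test_three_window_run_discarded(self):
        assert merge_windows(make_flag_tests([1, 1, 1])) == []

    def test_gap_splits_runs(self):
        peaks = merge_windows(make_flag_tests([1, 1, 1, 1, 0, 1, 1, 1, 1, 1]))
        assert [(p.t_start, p.t_end) for p in peaks] == [(0, 100), (125, 250)]
        assert [p.length for p in peaks] == [100, 125]

    def test_peak_invariants_on_merged_output(self):
        peaks = merge_windows(make_flag_tests([0, 1, 1, 1, 1, 1, 0, 0, 1, 1]))
        for p in peaks:
            assert p.length >= 100 and p.length % 25 == 0
            assert p.n_windows * 25 == p.length
            assert p.score == pytest.approx(-math.log10(p.q))

    def test_runs_do_not_cross_genes(self):
        ta = make_flag_tests([1, 1], gene="gA")
        tb = make_flag_tests([1, 1], gene="gB")
        # same window indices in two genes: no 4-run exists
        assert merge_windows(ta + tb) == []


def peak(gene, t0, t1):
    return Peak(gene, t0, t1, (t1 - t0) // 25, [], 2.0, 5.0, 1e-4, 1e-3)


class TestEvaluateAgainstTruth:
    def test_exact_match_scores_perfect(self):
        truth = SimulationTruth([TruthPeak("g", 100, 250, 8.0)])
        res = evaluate_against_truth([peak("g", 100, 250)], truth)
        assert res["recall"] == 1.0 and res["precision"] == 1.0

    def test_no_calls_gives_zero_recall(self):
        truth = SimulationTruth([TruthPeak("g", 100, 250, 8.0)])
        res = evaluate_against_truth([], truth)
        assert res["recall"] == 0.0 and res["precision"] is None

    def test_empty_truth_recall_undefined(self):
        res = evaluate_against_truth([peak("g", 0, 100)], SimulationTruth([]))
        assert res["recall"] is None

    def test_half_overlap_boundary_counts_as_recovered(self):
        # called covers exactly 50% of the 200-nt truth span
        truth = SimulationTruth([TruthPeak("g", 100, 300, 8.0)])
        res = evaluate_against_truth([peak("g", 200, 300)], truth)
        assert res["recall"] == 1.0
        assert res["precision"] == 1.0  # called lies entirely in truth

    def test_gene_identity_required(self):
        truth = SimulationTruth([TruthPeak("gA", 100, 250, 8.0)])
        res = evaluate_against_truth([peak("gB", 100, 250)], truth)
        assert res["recall"] == 0.0 and res["precision"] == 0.0
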
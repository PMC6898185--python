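"""Endpoint-pair (type 1) evidence: enumeration, clustering, tests, calls."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from barcodesv.dataset import GenomeIndex
from barcodesv.type1 import (TypeOneParams, best_square, call_type1,
                             classify_sv_type, cluster_points,
                             enumerate_fragment_pairs, merge_inversion_calls,
                             plane_coords, predict_breakpoints,
                             score_from_pvalues)
from barcodesv.type1 import test_barcode_coincidence as coincidence_test
from barcodesv.type1 import test_gap_lengths as gap_test

GENOME = GenomeIndex(("chr1",), np.array([100_000_000]))


def _frags(rows):
    df = pd.DataFrame(rows, columns=["chrom_id", "L", "R", "barcode_id"])
    df["n_reads"] = 5
    df["hap"] = 0
    return df


class TestEnumeration:
    def test_pair_counts(self):
        two = _frags([(0, 100, 200, 0), (0, 5000, 6000, 0)])
        assert len(enumerate_fragment_pairs(two, GENOME)) == 1
        ten = _frags([(0, i * 10_000, i * 10_000 + 500, 7)
                      for i in range(10)])
        assert len(enumerate_fragment_pairs(ten, GENOME)) == 45

    def test_canonical_ordering(self):
        pairs = enumerate_fragment_pairs(
            _frags([(0, 9000, 9500, 0), (0, 100, 200, 0)]), GENOME)
        assert pairs.iloc[0]["l1"] == 100          # smaller midpoint is F1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        rows = [(0, int(p), int(p) + 300, int(bc))
                for p, bc in zip(rng.integers(0, 10**7, 300),
                                 rng.integers(0, 50, 300))]
        frags = _frags(rows)
        pairs = enumerate_fragment_pairs(frags, GENOME)
        got = {frozenset((a, b))
               for a, b in zip(pairs["i1"], pairs["i2"])}
        bc = frags["barcode_id"].to_numpy()
        want = {frozenset((i, j))
                for i, j in itertools.combinations(range(len(frags)), 2)
                if bc[i] == bc[j]}
        assert got == want


class TestClustering:
    def test_trivial_cluster_and_support_threshold(self):
        x = np.array([0, 1, 0, 1, 0], dtype=float)
        y = np.array([0, 0, 1, 1, 0], dtype=float)
        assert len(cluster_points(x, y, G=10, min_support=5)) == 1
        assert len(cluster_points(x[:4], y[:4], G=10, min_support=5)) == 0

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        n, G = 400, 10_000
        x = rng.integers(0, 2_000_000, n).astype(float)
        y = rng.integers(0, 2_000_000, n).astype(float)
        # brute-force union-find over all pairs under Chebyshev < G
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                if abs(x[i] - x[j]) < G and abs(y[i] - y[j]) < G:
                    parent[find(i)] = find(j)
        labels = [find(i) for i in range(n)]
        want = {}
        for i, lab in enumerate(labels):
            want.setdefault(lab, set()).add(i)
        want_sets = {frozenset(v) for v in want.values() if len(v) >= 3}
        got_sets = {frozenset(c.tolist())
                    for c in cluster_points(x, y, G, min_support=3)}
        assert got_sets == want_sets


class TestBreakpointPrediction:
    def test_right_bottom_vertex_rule(self):
        x = np.array([990, 995, 1000], dtype=float)
        y = np.array([5000, 5003, 5010], dtype=float)
        assert predict_breakpoints(x, y, "RL") == (1000, 5000)

    def test_single_point(self):
        assert predict_breakpoints(np.array([7.0]), np.array([9.0]),
                                   "RL") == (7, 9)

    @pytest.mark.parametrize("plane,expected", [
        ("RL", (30, 100)), ("LR", (10, 300)),
        ("RR", (30, 300)), ("LL", (10, 100))])
    def test_vertex_per_plane(self, plane, expected):
        x = np.array([10.0, 20, 30])
        y = np.array([100.0, 200, 300])
        assert predict_breakpoints(x, y, plane) == expected

    def test_moving_square_retains_densest_window(self):
        x = np.concatenate([np.full(8, 1000.0), np.full(3, 50_000.0)])
        y = np.concatenate([np.full(8, 2000.0), np.full(3, 90_000.0)])
        mask = best_square(x, y, G=5000)
        assert mask.sum() == 8
        assert mask[:8].all()


class TestBarcodeCoincidence:
    def test_n_zero_gives_one(self):
        p1, _ = coincidence_test(0, 10**6, 10_000, 10**9)
        assert p1 == 1.0

    def test_matches_direct_summation_oracle(self):
        n, N, G, L = 5, 10**6, 10_000, 10_000 * 10**3  # p_hit = 1e-6
        p_hit = (G / L) ** 2
        p1, _ = coincidence_test(n, N, G, L)
        # brute force: extended-precision direct summation of the binomial
        # pmf via the multiplicative recurrence
        p = np.longdouble(p_hit)
        q = np.longdouble(1) - p
        pk = q ** N                       # pmf at k = 0
        cdf = np.longdouble(0)
        for k in range(n):
            cdf += pk
            pk = pk * (N - k) / (k + 1) * p / q
        brute = float(np.longdouble(1) - cdf)
        assert abs(p1 - brute) / brute < 1e-10

    def test_adjustment_modes(self):
        n, N, G, L = 8, 10**5, 5000, 10**7
        p1, adj_b = coincidence_test(n, N, G, L, "bonferroni")
        _, adj_p = coincidence_test(n, N, G, L, "printed")
        assert adj_b == pytest.approx(min(1.0, p1 * (L / G) ** 2), rel=1e-9)
        assert adj_p == pytest.approx(p1 * (G / L) ** 2, rel=1e-9)
        assert adj_p < p1 < adj_b

    @given(st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_in_n(self, n):
        a, _ = coincidence_test(n, 10**6, 10_000, 10**9)
        b, _ = coincidence_test(n + 1, 10**6, 10_000, 10**9)
        assert b <= a

    def test_n_exceeding_trials_fatal(self):
        with pytest.raises(ValueError):
            coincidence_test(11, 10, 100, 1000)


class TestGapLengths:
    def test_zero_mean_gap_gives_one(self):
        p2, _ = gap_test(np.zeros(5), 1e-3, 10**6)
        assert p2 == 1.0

    def test_matches_monte_carlo_oracle(self):
        """Tail of the mean of n Exp(lambda) gaps vs direct simulation."""
        n, lam, g_bar = 10, 1e-3, 2000.0
        gaps = np.full(n, g_bar)
        p2, _ = gap_test(gaps, lam, n_rp=n)  # unadjusted via n_rp=n
        rng = np.random.default_rng(8)
        reps = 400_000
        means = rng.exponential(1 / lam, (reps, n)).mean(axis=1)
        mc = (means >= g_bar).mean()
        se = math.sqrt(mc * (1 - mc) / reps)
        assert abs(p2 - mc) <= 3 * se

    def test_mean_gap_law_is_gamma(self):
        """Means of n iid Exp(lambda) gaps follow Gamma(n, n*lambda)."""
        n, lam = 7, 1e-3
        rng = np.random.default_rng(9)
        means = rng.exponential(1 / lam, (3000, n)).mean(axis=1)
        stat = sps.kstest(means, "gamma", args=(n, 0, 1 / (n * lam)))
        assert stat.pvalue > 0.01

    @given(st.floats(min_value=100, max_value=50_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_in_mean_gap(self, g):
        a, _ = gap_test(np.full(5, g), 1e-3, 10**6)
        b, _ = gap_test(np.full(5, g + 100), 1e-3, 10**6)
        assert b <= a

    def test_adjustment_factor(self):
        gaps = np.full(4, 3000.0)
        p2, adj = gap_test(gaps, 1e-3, n_rp=4000)
        assert adj == min(1.0, p2 * 4000 / 4)


class TestScoringAndClassification:
    def test_score_arithmetic(self):
        assert score_from_pvalues(1e-8, 1e-6) == pytest.approx(6.0)
        assert score_from_pvalues(1e-7, None) == pytest.approx(7.0)

    def test_both_tests_must_pass(self, del_vaf1):
        """A barcode-coincidence p above threshold kills the call even with
        overwhelming gap evidence (and vice versa)."""
        strict = TypeOneParams(p_threshold=1e-300)
        assert call_type1(del_vaf1.fragments, del_vaf1.genome,
                          del_vaf1.stats, strict) == [] or all(
            c.p_adjusted1 < 1e-300 for c in
            call_type1(del_vaf1.fragments, del_vaf1.genome, del_vaf1.stats,
                       strict))

    def test_classification(self):
        assert classify_sv_type("RL", 0, 0) == "DEL"
        assert classify_sv_type("LR", 0, 0) == "DUP"
        assert classify_sv_type("RR", 0, 0) == "INV"
        assert classify_sv_type("LL", 0, 0) == "INV"
        assert classify_sv_type("RL", 0, 1) == "TRA"


class TestEndToEndCalls:
    def test_deletion_called_exactly(self, del_vaf1):
        calls = call_type1(del_vaf1.fragments, del_vaf1.genome, del_vaf1.stats)
        dels = [c for c in calls if c.sv_type == "DEL"]
        assert len(dels) == 1
        truth = del_vaf1.truth[0]
        assert abs(dels[0].pos1 - truth.pos1) <= 20
        assert abs(dels[0].pos2 - truth.pos2) <= 20
        assert dels[0].n_support > 50
        assert dels[0].p_adjusted2 is not None   # colinear RL geometry

    def test_inversion_called_with_merged_planes(self, inv_vaf1):
        calls = call_type1(inv_vaf1.fragments, inv_vaf1.genome, inv_vaf1.stats)
        invs = [c for c in calls if c.sv_type == "INV"]
        assert len(invs) == 1
        truth = inv_vaf1.truth[0]
        assert abs(invs[0].pos1 - truth.pos1) <= del_tol(inv_vaf1)
        assert abs(invs[0].pos2 - truth.pos2) <= del_tol(inv_vaf1)
        assert invs[0].p_adjusted2 is None       # gap test inapplicable

    def test_null_dataset_silent(self, sv_free):
        assert call_type1(sv_free.fragments, sv_free.genome,
                          sv_free.stats) == []


def del_tol(prep):
    return prep.G


class TestInversionMerge:
    def test_consistent_rr_ll_pair_fuses(self):
        import dataclasses as dc
        from barcodesv.type1 import TypeOneCall
        base = dict(sv_type="INV", chrom1="chr1", chrom2="chr1",
                    p1=1e-9, p_adjusted1=1e-7, p2=None, p_adjusted2=None,
                    frag1_rows=np.array([0]), frag2_rows=np.array([1]),
                    passed=True)
        a = TypeOneCall(pos1=1000, pos2=9000, lin_b1=1000, lin_b2=9000,
                        plane="RR", n_support=6, score1=7.0, **base)
        b = TypeOneCall(pos1=1200, pos2=9100, lin_b1=1200, lin_b2=9100,
                        plane="LL", n_support=3, score1=5.0, **base)
        merged = merge_inversion_calls([a, b], G=5000)
        assert len(merged) == 1
        m = merged[0]
        assert m.n_support == 9
        assert m.score1 == 7.0
        assert m.lin_b1 == round((1000 * 6 + 1200 * 3) / 9)

    def test_distant_inversions_stay_separate(self):
        import dataclasses as dc
        from barcodesv.type1 import TypeOneCall
        base = dict(sv_type="INV", chrom1="chr1", chrom2="chr1",
                    p1=1e-9, p_adjusted1=1e-7, p2=None, p_adjusted2=None,
                    frag1_rows=np.array([0]), frag2_rows=np.array([1]),
                    passed=True)
        a = TypeOneCall(pos1=1000, pos2=9000, lin_b1=1000, lin_b2=9000,
                        plane="RR", n_support=6, score1=7.0, **base)
        b = TypeOneCall(pos1=500_000, pos2=900_000, lin_b1=500_000,
                        lin_b2=900_000, plane="LL", n_support=3, score1=5.0,
                        **base)
        assert len(merge_inversion_calls([a, b], G=5000)) == 2
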
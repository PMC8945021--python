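import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nchypergeom_wallenius

from _oracles import (
    bh_stepup,
    exact_hypergeom_pmf,
    exact_hypergeom_upper_tail,
    wallenius_urn_counts,
)
from regset.bias import PwfFit
from regset.data_model import AnnotationDatabase, Universe
from regset.stats import (
    ContingencyCounts,
    WalleniusParams,
    bh_adjust,
    hypergeom_pmf,
    hypergeom_pvalue,
    relative_enrichment,
    run_sea,
    wallenius_pmf,
    wallenius_pmf_counts,
    wallenius_pvalue,
)


def all_tables(max_M: int):
    for M in range(1, max_M + 1):
        for n in range(M + 1):
            for N in range(M + 1):
                lo, hi = max(0, N - (M - n)), min(n, N)
                for x in range(lo, hi + 1):
                    yield ContingencyCounts(x=x, n=n, N=N, M=M)


class TestContingencyCounts:
    def test_support_bounds_enforced(self):
        with pytest.raises(ValueError):
            ContingencyCounts(x=4, n=3, N=5, M=10)
        with pytest.raises(ValueError):
            ContingencyCounts(x=0, n=9, N=9, M=10)  # x >= N-(M-n) = 8

    def test_wallenius_D_formula(self):
        p = WalleniusParams(ContingencyCounts(x=2, n=5, N=6, M=20), w=3.0)
        assert p.D == pytest.approx(3.0 * 3 + (15 - 4))


class TestHypergeom:
    def test_forced_draw_has_probability_one(self):
        c = ContingencyCounts(x=3, n=10, N=3, M=10)
        assert hypergeom_pmf(c) == pytest.approx(1.0)

    def test_pmf_matches_exact_rational_value(self):
        c = ContingencyCounts(x=2, n=5, N=5, M=20)
        assert hypergeom_pmf(c) == pytest.approx(float(exact_hypergeom_pmf(2, 5, 5, 20)), rel=1e-12)

    def test_pmf_sums_to_one_over_support(self):
        tot = sum(hypergeom_pmf(ContingencyCounts(x=k, n=7, N=5, M=20)) for k in range(6))
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_pvalue_at_max_support_equals_pmf(self):
        c = ContingencyCounts(x=5, n=5, N=5, M=20)
        assert hypergeom_pvalue(c) == pytest.approx(hypergeom_pmf(c), rel=1e-12)

    def test_pvalue_at_min_support_is_one(self):
        c = ContingencyCounts(x=0, n=5, N=5, M=20)
        assert hypergeom_pvalue(c) == pytest.approx(1.0)

    def test_pvalue_matches_exact_rational_tail(self):
        c = ContingencyCounts(x=4, n=5, N=5, M=20)
        expected = float(exact_hypergeom_upper_tail(4, 5, 5, 20))
        assert hypergeom_pvalue(c) == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_exactness_small_M(self):
        for c in all_tables(12):
            expected = float(exact_hypergeom_pmf(c.x, c.n, c.N, c.M))
            assert hypergeom_pmf(c) == pytest.approx(expected, rel=5e-13, abs=1e-300)


class TestWallenius:
    def test_reduces_to_central_at_unit_odds(self):
        for c in all_tables(9):
            assert wallenius_pmf(WalleniusParams(c, 1.0)) == pytest.approx(
                hypergeom_pmf(c), abs=1e-10
            )

    @pytest.mark.parametrize("w", [0.2, 1.0, 2.0, 5.0])
    def test_pmf_normalises_over_support(self, w):
        c0 = ContingencyCounts(x=0, n=6, N=5, M=15)
        total = sum(wallenius_pmf_counts(k, c0, w) for k in range(6))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_outside_support_is_zero(self):
        c = ContingencyCounts(x=2, n=4, N=5, M=10)
        assert wallenius_pmf_counts(5, c, 2.0) == 0.0
        assert wallenius_pmf_counts(-1, c, 2.0) == 0.0

    def test_agrees_with_independent_library_implementation(self):
        cases = [(3, 4, 5, 10, 2.0), (2, 6, 5, 15, 0.5), (0, 7, 5, 30, 4.0),
                 (5, 30, 150, 1000, 3.0), (10, 25, 150, 1000, 1000.0)]
        for x, n, N, M, w in cases:
            mine = wallenius_pmf(WalleniusParams(ContingencyCounts(x=x, n=n, N=N, M=M), w))
            ref = float(nchypergeom_wallenius.pmf(x, M, n, N, w))
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_agrees_with_urn_simulation(self):
        rng = np.random.default_rng(99)
        x, n, N, M, w = 3, 4, 5, 10, 2.0
        draws = wallenius_urn_counts(M, n, N, w, size=50_000, rng=rng)
        est = float(np.mean(draws == x))
        se = float(np.sqrt(est * (1 - est) / draws.size))
        mine = wallenius_pmf(WalleniusParams(ContingencyCounts(x=x, n=n, N=N, M=M), w))
        assert abs(mine - est) < 3 * se

    def test_tail_sums_to_one_from_support_minimum(self):
        c = ContingencyCounts(x=0, n=5, N=6, M=18)
        assert wallenius_pvalue(c, 3.0) == pytest.approx(1.0, abs=1e-8)

    def test_upper_tail_monotone_in_odds(self):
        # drawing in-term elements with higher odds can only fatten the tail
        c = ContingencyCounts(x=3, n=8, N=10, M=30)
        tails = [wallenius_pvalue(c, w) for w in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a - 1e-10 for a, b in zip(tails, tails[1:]))

    def test_degenerate_single_outcome(self):
        # input takes the whole background: the only outcome has mass 1
        c = ContingencyCounts(x=4, n=4, N=10, M=10)
        assert wallenius_pmf(WalleniusParams(c, 2.5)) == 1.0

    def test_nonpositive_odds_rejected(self):
        with pytest.raises(ValueError):
            WalleniusParams(ContingencyCounts(x=1, n=2, N=2, M=5), w=0.0)


class TestBhAdjust:
    def test_worked_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_equal_pvalues_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_closed_form_stepup(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_stepup(pvals), rel=1e-12, abs=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_invariant_to_input_permutation(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = bh_adjust(pvals)
        permuted = bh_adjust([pvals[i] for i in perm])
        assert [permuted[perm.index(i)] for i in range(len(pvals))] == pytest.approx(direct)


class TestRelativeEnrichment:
    def test_arithmetic(self):
        c = ContingencyCounts(x=5, n=50, N=10, M=1000)
        assert relative_enrichment(c, n_db=50, M_db=1000) == pytest.approx(10.0)

    def test_whole_term_input_in_single_term_db_scores_one(self):
        c = ContingencyCounts(x=5, n=5, N=5, M=5)
        assert relative_enrichment(c, n_db=5, M_db=5) == pytest.approx(1.0)

    def test_zero_overlap_scores_zero(self):
        c = ContingencyCounts(x=0, n=5, N=10, M=100)
        assert relative_enrichment(c, n_db=5, M_db=100) == 0.0

    def test_zero_denominator_rejected(self):
        c = ContingencyCounts(x=0, n=0, N=5, M=100)
        with pytest.raises(ValueError):
            relative_enrichment(c, n_db=0, M_db=100)


class TestRunSea:
    @pytest.fixture
    def db20(self) -> AnnotationDatabase:
        genes = [f"g{i}" for i in range(20)]
        return AnnotationDatabase("db", {
            "A": ("a", frozenset(genes[:5])),
            "B": ("b", frozenset(genes[5:12])),
            "C": ("c", frozenset(genes[12:20])),
        })

    @pytest.fixture
    def uni20(self) -> Universe:
        return Universe("custom", frozenset(f"g{i}" for i in range(20)))

    def test_perfect_term_hit_gets_the_exact_extreme_pvalue(self, db20, uni20):
        from math import comb
        rows = run_sea(frozenset(f"g{i}" for i in range(5)), db20, uni20)
        top = rows[0]
        assert top.term_id == "A" and top.counts.x == 5 and top.counts.n == 5
        assert top.pvalue == pytest.approx(1 / comb(20, 5), rel=1e-10)

    def test_uniform_pwf_reduces_wallenius_to_hypergeom(self, db20, uni20):
        genes = sorted(uni20.elements)
        pwf = PwfFit(covariate={g: 1.0 for g in genes},
                     weight={g: 0.25 for g in genes}, fit_meta={})
        inp = frozenset(["g0", "g1", "g6", "g13"])
        hyper = run_sea(inp, db20, uni20, method="hypergeom")
        wall = run_sea(inp, db20, uni20, method="wallenius", pwf=pwf)
        for h, w in zip(hyper, wall):
            assert h.term_id == w.term_id
            assert w.pvalue == pytest.approx(h.pvalue, abs=1e-8)
            assert w.w == pytest.approx(1.0)

    def test_terms_without_input_overlap_are_absent(self, db20, uni20):
        rows = run_sea(frozenset({"g0"}), db20, uni20)
        assert [r.term_id for r in rows] == ["A"]

    def test_padj_never_below_pvalue_and_rows_sorted(self, db20, uni20):
        rows = run_sea(frozenset(["g0", "g1", "g2", "g6", "g13"]), db20, uni20)
        assert all(r.padj >= r.pvalue for r in rows)
        keys = [(r.padj, r.pvalue, r.term_id) for r in rows]
        assert keys == sorted(keys)

    def test_wallenius_without_pwf_rejected(self, db20, uni20):
        with pytest.raises(ValueError, match="PWF"):
            run_sea(frozenset({"g0"}), db20, uni20, method="wallenius")

    def test_disjoint_input_rejected(self, db20, uni20):
        with pytest.raises(ValueError, match="background"):
            run_sea(frozenset({"zz"}), db20, uni20)

    def test_support_size_equals_x(self, db20, uni20):
        rows = run_sea(frozenset(["g0", "g1", "g6"]), db20, uni20)
        for r in rows:
            assert len(r.support) == r.counts.x
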
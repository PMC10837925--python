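"""Exact-test core: hypergeometric PMF, two-sided Fisher, Woolf CI, burden table."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import oligoburden as ob
from oligoburden.burden_stats import ContingencyResult, Z_95


def fisher_oracle(a, b, c, d):
    """Exhaustive-enumeration two-sided Fisher with exact rational arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    if K in (0, N) or n in (0, N):
        return 1.0
    total = comb(N, n)
    pmf = {
        k: Fraction(comb(K, k) * comb(N - K, n - k), total)
        for k in range(max(0, K + n - N), min(K, n) + 1)
    }
    obs = pmf[a]
    return float(min(1, sum(p for p in pmf.values() if p <= obs * (1 + Fraction(1, 10**7)))))


class TestLogHypergeomPmf:
    def test_closed_form_cohort_scale(self):
        # P[X=2] for 2 carriers among 93 draws from 558 = C(93,2)/C(558,2)
        expected = math.log(4278 / 155403)
        assert ob.log_hypergeom_pmf(2, 558, 2, 93) == pytest.approx(expected, rel=1e-12)

    def test_certain_event_is_log_one(self):
        assert ob.log_hypergeom_pmf(0, 10, 0, 5) == 0.0

    def test_out_of_support_is_minus_inf(self):
        assert ob.log_hypergeom_pmf(3, 10, 2, 5) == -math.inf
        assert ob.log_hypergeom_pmf(-1, 10, 2, 5) == -math.inf

    @pytest.mark.parametrize("N,K,n", [(10, 3, 4), (25, 10, 7), (60, 30, 20)])
    def test_pmf_normalises(self, N, K, n):
        s = sum(
            math.exp(ob.log_hypergeom_pmf(k, N, K, n))
            for k in range(max(0, K + n - N), min(K, n) + 1)
        )
        assert s == pytest.approx(1.0, abs=1e-12)


class TestFisherTwoSided:
    # printed per-gene p-values of the study's burden table
    @pytest.mark.parametrize(
        "cells,expected,rel",
        [
            ((4, 89, 0, 465), 7.31e-4, 5e-3),   # closed form C(93,4)/C(558,4)
            ((2, 91, 0, 465), 2.75e-2, 5e-3),   # closed form C(93,2)/C(558,2)
            ((9, 84, 8, 457), 5.28e-4, 5e-3),
            ((11, 82, 13, 452), 5.98e-4, 5e-3),
            ((4, 89, 1, 464), 3.18e-3, 5e-3),
            ((21, 72, 15, 450), 4.04e-9, 5e-3),
        ],
    )
    def test_published_tables(self, cells, expected, rel):
        assert ob.fisher_two_sided(*cells) == pytest.approx(expected, rel=rel)

    def test_zero_cell_row_matches_closed_form(self):
        # only the observed table is as or less probable than itself
        assert ob.fisher_two_sided(2, 91, 0, 465) == pytest.approx(
            comb(93, 2) / comb(558, 2), rel=1e-12
        )

    def test_degenerate_margins_give_one(self):
        assert ob.fisher_two_sided(0, 93, 0, 465) == 1.0
        assert ob.fisher_two_sided(0, 0, 3, 4) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ob.fisher_two_sided(-1, 2, 3, 4)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle_and_scipy(self, a, b, c, d):
        p = ob.fisher_two_sided(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-7
        )

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_group_swap_symmetry(self, a, b, c, d):
        assert ob.fisher_two_sided(a, b, c, d) == pytest.approx(
            ob.fisher_two_sided(c, d, a, b), rel=1e-12
        )

    def test_doubling_variant_bounded_and_close(self):
        p_pmf = ob.fisher_two_sided(9, 84, 8, 457)
        p_dbl = ob.fisher_two_sided(9, 84, 8, 457, method="double")
        assert 0 < p_dbl <= 1
        assert p_dbl >= p_pmf * 0.5  # same order of magnitude


class TestSampleOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((9, 84, 8, 457), 6.12),
            ((11, 82, 13, 452), 4.66),
            ((4, 89, 1, 464), 20.85),
            ((4, 89, 3, 462), 6.92),
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_published_values(self, cells, expected):
        assert ob.sample_odds_ratio(*cells) == pytest.approx(expected, abs=5e-3)

    def test_zero_control_carriers_is_infinite(self):
        assert ob.sample_odds_ratio(4, 89, 0, 465) == math.inf

    def test_no_carriers_is_undefined(self):
        assert math.isnan(ob.sample_odds_ratio(0, 93, 0, 465))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reciprocal_under_column_swap(self, a, b, c, d):
        assert ob.sample_odds_ratio(a, b, c, d) * ob.sample_odds_ratio(
            b, a, d, c
        ) == pytest.approx(1.0, rel=1e-12)


class TestWoolfCI:
    @pytest.mark.parametrize(
        "cells,lo,hi",
        [
            ((9, 84, 8, 457), 2.30, 16.31),
            ((11, 82, 13, 452), 2.02, 10.77),
            ((5, 88, 3, 462), 2.05, 37.28),
            ((21, 72, 15, 450), 4.31, 17.76),
            ((5, 88, 2, 463), 2.51, 68.87),
        ],
    )
    def test_published_intervals_to_2dp(self, cells, lo, hi):
        got_lo, got_hi = ob.woolf_ci(*cells)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_zero_cell_contract(self):
        lo, hi = ob.woolf_ci(4, 89, 0, 465)
        assert math.isnan(lo) and hi == math.inf

    def test_log_symmetric_about_or(self):
        a, b, c, d = 9, 84, 8, 457
        lo, hi = ob.woolf_ci(a, b, c, d)
        orr = ob.sample_odds_ratio(a, b, c, d)
        assert math.log(hi) - math.log(orr) == pytest.approx(
            math.log(orr) - math.log(lo), rel=1e-10
        )

    def test_interval_shrinks_toward_or_as_cells_scale(self):
        widths = []
        for k in (1, 10, 100):
            lo, hi = ob.woolf_ci(9 * k, 84 * k, 8 * k, 457 * k)
            widths.append(math.log(hi) - math.log(lo))
        assert widths[0] > widths[1] > widths[2]
        lo, hi = ob.woolf_ci(9000, 84000, 8000, 457000)
        assert lo == pytest.approx(6.12, abs=0.2)

    def test_z_matches_95_percent_quantile(self):
        assert Z_95 == pytest.approx(scipy.stats.norm.ppf(0.975), abs=1e-6)


class TestContingencyResult:
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ci_brackets_or_when_defined(self, a, b, c, d):
        r = ContingencyResult.from_cells(a, b, c, d)
        assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert 0 < r.p_value <= 1


class TestGeneBurden:
    def test_reference_cohort_top_ranks(self, reference_matrix):
        bt = ob.gene_burden(reference_matrix)
        assert bt.rank["RAD52"] == 1
        assert bt.rank["MSH6"] == 2
        assert bt.quantile["RAD52"] == pytest.approx(1 / 191)

    def test_significant_set_is_the_fifteen_reference_genes(self, reference_matrix):
        bt = ob.gene_burden(reference_matrix)
        sig = {g for g, r in bt.rows.items() if r.p_value < 0.05}
        assert len(sig) == 15
        assert {"RAD52", "MSH6", "AR", "TP63", "FANCG", "GDF9", "NUP107"} <= sig

    def test_matches_cell_by_cell_oracle(self, small_random_matrix):
        _, matrix = small_random_matrix
        bt = ob.gene_burden(matrix)
        mask = matrix.case_mask
        for j, gene in enumerate(matrix.genes):
            a = int(matrix.carries[mask, j].sum())
            c = int(matrix.carries[~mask, j].sum())
            b, d = int(mask.sum()) - a, int((~mask).sum()) - c
            r = bt.rows[gene]
            assert (r.a, r.b, r.c, r.d) == (a, b, c, d)
            assert r.p_value == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_ranks_are_a_permutation_and_quantiles_in_unit_interval(self, reference_matrix):
        bt = ob.gene_burden(reference_matrix)
        assert sorted(bt.rank.values()) == list(range(1, 192))
        assert all(0 < q <= 1 for q in bt.quantile.values())
        ordered = sorted(bt.rank, key=bt.rank.get)
        ps = [bt.rows[g].p_value for g in ordered]
        assert ps == sorted(ps)

    def test_carrier_free_gene_has_p_one_and_nan_or(self, reference_matrix):
        bt = ob.gene_burden(reference_matrix)
        r = bt.rows["GONP01"]  # no carriers in either group
        assert r.p_value == 1.0 and math.isnan(r.odds_ratio)

    def test_single_group_matrix_rejected(self, reference_cohort):
        cases_only = [s for s in reference_cohort.samples if s.group == "case"]
        tuples = [t for t in reference_cohort.variant_tuples if t[0].startswith("P")]
        m = ob.build_carrier_matrix(tuples, cases_only, reference_cohort.panel)
        with pytest.raises(ValueError):
            ob.gene_burden(m)


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    ps = np.array([0.001, 0.02, 0.03, 0.5, 0.8])
    adj = ob.burden_stats.benjamini_hochberg(ps)
    expected = multipletests(ps, method="fdr_bh")[1]
    assert adj == pytest.approx(expected)
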
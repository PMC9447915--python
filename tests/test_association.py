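"""2x2 enrichment statistics: OR, Woolf CI, chi-squared, Fisher, test selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom
from statsmodels.stats.contingency_tables import Table2x2

from burdenscope import (
    AssociationConfig,
    CohortCounts,
    ContingencyTable,
    Convention,
    TestKind as StatTest,
    ZeroCellPolicy,
    associate,
    build_table,
    fisher_exact,
    odds_ratio,
    pearson_chi2,
    select_test,
    woolf_ci,
)
from burdenscope.datasets import AMD_COHORTS

SCOPE = ContingencyTable(84, 3159, 221, 64382)
FINBB = ContingencyTable(2, 941, 3, 12559)
KAVANAGH = ContingencyTable(54, 2212, 3, 1397)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by exhaustive probability-mass enumeration."""
    n_total = table.total
    k_carriers = table.a + table.c
    n_cases = table.n_cases
    rv = hypergeom(n_total, k_carriers, n_cases)
    support = range(max(0, n_cases + k_carriers - n_total), min(k_carriers, n_cases) + 1)
    p_obs = rv.pmf(table.a)
    return float(sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-12)))


def small_tables(max_cell=40):
    cells = st.integers(0, max_cell)
    return st.tuples(cells, cells, cells, cells).filter(
        lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0
    )


class TestBuildTable:
    def test_derives_noncarrier_cells(self):
        cases, controls = AMD_COHORTS["SCOPE"]
        assert build_table(cases, controls) == SCOPE
        cases, controls = AMD_COHORTS["FINBB"]
        assert build_table(cases, controls) == FINBB

    def test_zero_carriers_both_arms_valid(self):
        t = build_table(CohortCounts("x", 100, 0), CohortCounts("y", 200, 0))
        assert (t.a, t.b, t.c, t.d) == (0, 100, 0, 200)

    def test_allele_convention_refused(self):
        allele = CohortCounts("alleles", 100, 4, Convention.ALLELE_FREQUENCY)
        with pytest.raises(ValueError, match="convert_convention"):
            build_table(allele, CohortCounts("y", 200, 0))


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [(SCOPE, 7.75), (KAVANAGH, 11.37), (FINBB, 8.90)],
    )
    def test_published_cohort_values(self, table, expected):
        assert round(odds_ratio(table), 2) == expected

    def test_equal_frequencies_give_unity(self):
        assert odds_ratio(ContingencyTable(5, 95, 10, 190)) == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        t = ContingencyTable(0, 10, 5, 95)
        assert odds_ratio(t, ZeroCellPolicy.HALDANE) == pytest.approx(
            (0.5 * 95.5) / (10.5 * 5.5)
        )

    def test_error_policy_refuses_zero_cell(self):
        with pytest.raises(ValueError, match="empty cell"):
            odds_ratio(ContingencyTable(0, 10, 5, 95), ZeroCellPolicy.ERROR)

    @given(small_tables().filter(lambda t: 0 not in t))
    @settings(max_examples=100, deadline=None)
    def test_row_and_column_swap_invariance(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        swapped = ContingencyTable(d, c, b, a)  # both rows and both columns
        assert odds_ratio(swapped) == pytest.approx(odds_ratio(t))

    @given(small_tables().filter(lambda t: 0 not in t))
    @settings(max_examples=100, deadline=None)
    def test_transposing_arms_inverts_or_and_ci(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        flipped = ContingencyTable(c, d, a, b)
        assert odds_ratio(flipped) == pytest.approx(1.0 / odds_ratio(t))
        low, high = woolf_ci(t)
        flow, fhigh = woolf_ci(flipped)
        assert flow == pytest.approx(1.0 / high)
        assert fhigh == pytest.approx(1.0 / low)


class TestWoolfCI:
    @pytest.mark.parametrize(
        "table, low, high",
        [(KAVANAGH, 3.55, 36.43), (FINBB, 1.49, 53.31), (SCOPE, 6.02, 9.99)],
    )
    def test_published_cohort_intervals(self, table, low, high):
        got_low, got_high = woolf_ci(table, 0.95)
        # agreement at the printed two-decimal precision (one unit in the
        # last place; display rounding of the published bounds is not
        # bit-reproducible)
        assert got_low == pytest.approx(low, abs=0.0101)
        assert got_high == pytest.approx(high, abs=0.0101)

    def test_matches_statsmodels_logit_interval(self):
        sm = Table2x2(np.array([[84, 3159], [221, 64382]]))
        assert woolf_ci(SCOPE, 0.95) == pytest.approx(sm.oddsratio_confint(0.05), rel=1e-9)

    def test_contains_point_estimate_and_widens_with_level(self):
        for t in (SCOPE, KAVANAGH, FINBB):
            point = odds_ratio(t)
            low90, high90 = woolf_ci(t, 0.90)
            low99, high99 = woolf_ci(t, 0.99)
            assert low99 < low90 < point < high90 < high99

    def test_interval_collapses_as_level_vanishes(self):
        low, high = woolf_ci(SCOPE, 1e-9)
        assert low == pytest.approx(high, rel=1e-6)
        assert low == pytest.approx(odds_ratio(SCOPE), rel=1e-3)


class TestPearsonChi2:
    def test_equal_proportions_give_zero_statistic(self):
        stat, p = pearson_chi2(ContingencyTable(5, 95, 10, 190))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_returns_null(self):
        assert pearson_chi2(ContingencyTable(0, 50, 0, 100)) == (0.0, 1.0)

    def test_strong_enrichment_is_overwhelming(self):
        _, p = pearson_chi2(SCOPE)
        assert p < 1e-50

    def test_statistic_equals_pooled_z_squared(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            p1_hat, p0_hat = t.a / t.n_cases, t.c / t.n_controls
            pooled = (t.a + t.c) / t.total
            z = (p1_hat - p0_hat) / math.sqrt(
                pooled * (1 - pooled) * (1 / t.n_cases + 1 / t.n_controls)
            )
            stat, _ = pearson_chi2(t, continuity=False)
            assert stat == pytest.approx(z * z, rel=1e-9)

    def test_yates_correction_shrinks_statistic(self):
        stat_plain, _ = pearson_chi2(FINBB, continuity=False)
        stat_yates, _ = pearson_chi2(FINBB, continuity=True)
        assert stat_yates < stat_plain


class TestFisherExact:
    def test_published_small_cohort_p(self):
        # two-sided probability-mass p for the FINBB table, printed as 4.2E-02
        p = fisher_exact(FINBB)
        assert p == pytest.approx(fisher_enumeration_oracle(FINBB), rel=1e-8)
        assert round(p, 3) == 0.042

    def test_null_table_p_is_one(self):
        assert fisher_exact(ContingencyTable(0, 50, 0, 100)) == 1.0

    @given(small_tables(max_cell=7))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_on_small_tables(self, cells):
        t = ContingencyTable(*cells)
        assert fisher_exact(t) == pytest.approx(fisher_enumeration_oracle(t), rel=1e-8)


class TestSelectTest:
    def test_small_carrier_cells_route_to_fisher(self):
        assert select_test(FINBB) is StatTest.FISHER_EXACT
        assert select_test(KAVANAGH) is StatTest.FISHER_EXACT  # control carriers = 3

    def test_large_carrier_cells_route_to_chi2(self):
        assert select_test(SCOPE) is StatTest.PEARSON_CHI2

    def test_boundary_is_strict(self):
        assert select_test(ContingencyTable(5, 95, 5, 95)) is StatTest.PEARSON_CHI2
        assert select_test(ContingencyTable(4, 96, 5, 95)) is StatTest.FISHER_EXACT


class TestAssociate:
    def test_uk_biobank_row(self):
        cases, controls = AMD_COHORTS["UK Biobank"]
        res = associate(cases, controls)
        assert round(res.odds_ratio, 2) == 3.12
        assert round(res.ci_low, 2) == 2.25
        assert round(res.ci_high, 2) == 4.33
        assert res.test_used is StatTest.PEARSON_CHI2

    def test_iamdgc_row(self):
        cases, controls = AMD_COHORTS["IAMDGC"]
        res = associate(cases, controls)
        assert round(res.odds_ratio, 2) == 4.14
        assert round(100 * res.case_frequency, 3) == 1.220

    def test_null_cohorts(self):
        res = associate(CohortCounts("cases", 100, 0), CohortCounts("controls", 100, 0))
        assert res.test_used is StatTest.FISHER_EXACT
        assert res.p_value == 1.0
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.correction_applied

    def test_ci_level_configurable(self):
        cases, controls = AMD_COHORTS["SCOPE"]
        narrow = associate(cases, controls, AssociationConfig(ci_level=0.5))
        wide = associate(cases, controls, AssociationConfig(ci_level=0.99))
        assert narrow.ci_high - narrow.ci_low < wide.ci_high - wide.ci_low
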
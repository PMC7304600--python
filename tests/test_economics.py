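"""Costing, ICER/dominance classification, league-table ordering and
portfolio arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ace.bundle import CostComponent, InterventionSpec
from ace.economics import (
    COST_EFFECTIVE,
    COST_SAVING_HEALTH_NEUTRAL,
    CostingRules,
    DOMINANT,
    DOMINATED,
    NOT_COST_EFFECTIVE,
    build_league_table,
    compute_icer,
    cost_intervention,
    make_result,
    mid50_range,
    portfolio_summary,
)


def _spec_with(components):
    return InterventionSpec(
        name="c", classification="program", target_age_lo=18,
        target_age_hi=100, target_sexes="both", effect_type="bmi_delta",
        effect_size=-0.1, effect_se=0.01, uptake=0.5,
        cost_components=tuple(components))


class TestCosting:
    def test_no_components_costs_nothing(self):
        c = cost_intervention(_spec_with([]))
        assert c.total_discounted == 0.0
        assert c.first3y_undiscounted == 0.0

    def test_single_component_year_zero(self):
        c = cost_intervention(_spec_with([
            CostComponent("x", "federal_govt", 100.0, 0, 0)]))
        assert c.total_discounted == pytest.approx(100.0)
        assert c.first3y_undiscounted == pytest.approx(100.0)

    def test_time_cost_valued_with_oncosts_and_leave_loading(self):
        # 10 hours at wage 40, public sector: 10*40*1.13*1.175 = 531.10
        rules = CostingRules(wage_rate=40.0)
        c = cost_intervention(_spec_with([
            CostComponent("t", "state_govt", 10.0, 0, 0, time_cost=True)]),
            rules)
        assert c.total_discounted == pytest.approx(10 * 40 * 1.13 * 1.175)
        private = cost_intervention(_spec_with([
            CostComponent("t", "industry", 10.0, 0, 0, time_cost=True)]),
            rules)
        assert private.total_discounted == pytest.approx(10 * 40 * 1.14 * 1.175)

    def test_indexing_to_2010(self):
        rules = CostingRules(
            health_price_index={2008: 0.9, 2010: 1.0},
            gdp_index={2008: 0.95, 2010: 1.0})
        c = cost_intervention(_spec_with([
            CostComponent("h", "federal_govt", 90.0, 0, 0,
                          health_related=True, source_year=2008)]), rules)
        assert c.total_discounted == pytest.approx(90.0 / 0.9)

    def test_missing_index_year_rejected(self):
        with pytest.raises(KeyError, match="index"):
            cost_intervention(_spec_with([
                CostComponent("h", "federal_govt", 90.0, 0, 0,
                              source_year=1999)]))

    def test_multi_year_discounting(self):
        c = cost_intervention(_spec_with([
            CostComponent("x", "federal_govt", 100.0, 0, 2)]),
            discount_rate=0.03)
        assert c.total_discounted == pytest.approx(
            100 * (1 + 1 / 1.03 + 1 / 1.03**2))
        assert c.first3y_undiscounted == pytest.approx(300.0)


class TestICER:
    @pytest.mark.parametrize("net, halys, expected_class, expected_icer", [
        (-100.0, 50.0, DOMINANT, None),
        (1_000_000.0, 100.0, COST_EFFECTIVE, 10_000.0),
        (10_000_000.0, 100.0, NOT_COST_EFFECTIVE, 100_000.0),
        (5.0, -1.0, DOMINATED, None),
        (0.0, 0.0, COST_SAVING_HEALTH_NEUTRAL, None),
        (3.0, 0.0, NOT_COST_EFFECTIVE, float("inf")),
    ])
    def test_sign_partition(self, net, halys, expected_class, expected_icer):
        icer, klass = compute_icer(net, halys)
        assert klass == expected_class
        if expected_icer is None:
            assert icer is None
        else:
            assert icer == expected_icer

    def test_printed_menu_labelling_arithmetic(self):
        # cost 170M, offsets 672M, 63,492 HALYs -> net -502M, dominant
        res = make_result("menu", "regulatory", 63_492.0, 170e6, 672e6,
                          first3y=37e6)
        assert res.net_cost == pytest.approx(-502e6)
        assert res.dominance_class == DOMINANT

    @given(st.floats(0.1, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_currency_rescaling_scales_icer_not_class(self, k):
        icer, klass = compute_icer(2_000_000.0, 80.0)
        icer_k, klass_k = compute_icer(2_000_000.0 * k, 80.0, wtp=50_000.0 * k)
        assert icer_k == pytest.approx(icer * k, rel=1e-12)
        assert klass_k == klass


class TestLeagueTable:
    def test_reproduces_printed_ordering(self, league_results):
        ranked = build_league_table(league_results)
        from ace.fixtures import load_league_fixture
        printed = list(load_league_fixture()["intervention"])
        assert [r.name for r in ranked] == printed

    def test_dominant_block_precedes_and_is_sorted_by_halys(self, league_results):
        ranked = build_league_table(league_results)
        classes = [r.dominance_class for r in ranked]
        first_nondominant = classes.index(COST_EFFECTIVE)
        assert all(c == DOMINANT for c in classes[:first_nondominant])
        halys = [r.halys_gained for r in ranked[:first_nondominant]]
        assert halys == sorted(halys, reverse=True)
        icers = [r.icer for r in ranked[first_nondominant:]]
        assert icers == sorted(icers)

    def test_is_permutation_and_idempotent(self, league_results):
        ranked = build_league_table(league_results)
        assert sorted(r.name for r in ranked) == sorted(
            r.name for r in league_results)
        assert build_league_table(ranked) == ranked

    def test_equal_dominant_halys_tie_breaks_alphabetically(self):
        rows = [make_result(n, "program", 10.0, 5.0, 100.0) for n in "bca"]
        ranked = build_league_table(rows)
        assert [r.name for r in ranked] == ["a", "b", "c"]

    def test_single_result_ranks_first(self):
        res = make_result("only", "program", 1.0, 10.0, 0.0)
        assert build_league_table([res])[0] is res


class TestMid50:
    def test_matches_brute_force_rank_dropping(self):
        rng = np.random.default_rng(4)
        for n in (7, 8, 15, 16, 17):
            vals = rng.normal(size=n)
            lo, hi = mid50_range(vals)
            s = np.sort(vals)
            k = n // 4
            kept = s[k:n - k]
            assert (lo, hi) == (kept.min(), kept.max())


class TestPortfolio:
    def test_printed_summary_arithmetic(self, league_results):
        s = portfolio_summary(league_results)
        assert s["n_dominant"] == 11
        assert s["n_cost_effective"] == 16
        assert s["halys_mid50"] == (28_981.0, 73_883.0)
        assert s["cost_mid50"] == (15e6, 170e6)
        assert s["net_cost_mid50"] == (-638e6, 2e6)
        assert s["icer_range_nondominant"] == (1_728.0, 28_703.0)
        assert s["first3y_budget"] > 3e9
        # mean cost of non-dominant interventions about nine-fold larger
        assert s["cost_ratio_nondominant_over_dominant"] == pytest.approx(
            9.0, abs=1.0)
        # mean health gains of dominant block under three-fold larger
        assert 1.0 < s["halys_ratio_dominant_over_nondominant"] < 3.0

    def test_counts_by_classification(self, league_results):
        s = portfolio_summary(league_results)
        assert s["n_regulatory"] == 9
        assert s["n_program"] == 7
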
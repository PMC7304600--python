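"""Multi-state life table engine: disease process, conservation,
null-scenario invariance, discounting, monotonicity."""

import numpy as np
import pytest

import ace
from ace.bundle import InterventionSpec
from ace.lifetable import (
    Evaluator,
    N_YEARS,
    evaluate_intervention,
    run_disease_process,
)


class TestDiseaseProcess:
    def test_no_incidence_no_initial_prevalence_stays_empty(self):
        tr = run_disease_process([0.0] * 10, [0.1] * 10, [0.0] * 10)
        assert not tr.C.any()
        assert tr.S[-1] == pytest.approx(1.0)

    def test_hand_iteration_in_raw_rate_mode(self):
        # i=0.01, f=0.1, r=0: C(1)=0.01, C(2)=0.01*0.9+0.99*0.01=0.0189
        tr = run_disease_process([0.01] * 2, [0.1] * 2, [0.0] * 2,
                                 convert_rates=False)
        assert tr.C[1] == pytest.approx(0.01)
        assert tr.S[1] == pytest.approx(0.99)
        assert tr.C[2] == pytest.approx(0.0189)

    def test_halved_incidence_scale_halves_first_year_cases(self):
        full = run_disease_process([0.02] * 3, [0.05] * 3, [0.0] * 3,
                                   incidence_scale=[1.0] * 3)
        half = run_disease_process([0.02] * 3, [0.05] * 3, [0.0] * 3,
                                   incidence_scale=[0.5] * 3)
        assert half.new_cases[0] == pytest.approx(
            0.5 * full.new_cases[0], rel=1e-2)

    def test_mass_conservation_to_1e9(self):
        rng = np.random.default_rng(0)
        n = 80
        tr = run_disease_process(rng.uniform(0, 0.05, n),
                                 rng.uniform(0, 0.1, n),
                                 rng.uniform(0, 0.02, n))
        total = tr.S[1:] + tr.C[1:] + np.cumsum(tr.d_mort)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_prevalence_non_increasing_without_incidence(self):
        tr = run_disease_process([0.0] * 20, [0.05] * 20, [0.01] * 20,
                                 S0=0.8, C0=0.2)
        assert np.all(np.diff(tr.C) <= 1e-15)

    def test_raw_mode_rejects_oversized_rates(self):
        with pytest.raises(ValueError, match="rate too large"):
            run_disease_process([1.5] * 3, [1.2] * 3, [0.0] * 3, S0=0.0,
                                C0=1.0, convert_rates=False)


class TestNullInvariance:
    def test_zero_pif_table_reproduces_baseline_to_1e12(self, evaluator):
        base = evaluator.run_baseline()
        null = evaluator.run_scenario(np.zeros((9, evaluator.n_s, N_YEARS)))
        assert null.total_halys == pytest.approx(base.total_halys, rel=1e-12)
        assert null.total_cost == pytest.approx(base.total_cost, rel=1e-12)
        np.testing.assert_allclose(null.haly_stream, base.haly_stream,
                                   rtol=1e-12)

    def test_zero_effect_spec_yields_zero_increments(self, bundle):
        spec = bundle.get_intervention("ssb_tax_20pct")
        zero = InterventionSpec(**{**{f: getattr(spec, f) for f in (
            "name", "classification", "target_age_lo", "target_age_hi",
            "target_sexes", "effect_type", "effect_se", "uptake",
            "implementation_years", "maintenance_type", "maintenance_end_year",
            "cost_components")}, "effect_size": 0.0})
        out = evaluate_intervention(bundle, zero)
        assert out.halys_gained == pytest.approx(0.0, abs=1e-9)
        assert out.cost_offsets == pytest.approx(0.0, abs=1e-6)


class TestOutcomeAccounting:
    def test_totals_equal_stream_sums(self, evaluator, bundle):
        out = evaluator.evaluate(bundle.get_intervention("menu_kj_labelling"))
        assert out.scenario.total_halys == pytest.approx(
            out.scenario.haly_stream.sum(), abs=1e-6)
        assert out.scenario.total_cost == pytest.approx(
            out.scenario.cost_stream.sum(), abs=1e-6)

    def test_survivorship_non_increasing(self, bundle):
        # undiscounted single-cohort annuity: constant survival of 1 for the
        # whole horizon gives L = horizon years per person
        b = bundle.copy()
        pop = b.population.copy()
        pop["count"] = 0.0
        pop.loc[(pop["age"] == 90) & (pop["sex"] == "female"), "count"] = 1.0
        pop["mortality_all_cause"] = 0.0
        pop["yld_all_cause"] = 0.0
        b.population = pop
        dis = b.diseases.copy()
        dis["incidence"] = 0.0
        dis["case_fatality"] = 0.0
        b.diseases = dis
        ev = Evaluator(b, discount_rate=0.0)
        base = ev.run_baseline()
        # ages 90..100 inclusive: 11 modelled years, survival 1 throughout
        assert base.total_halys == pytest.approx(11.0, abs=1e-9)

    def test_discounted_unit_stream_annuity(self):
        # 1 per year for years 0..2 at 3%: 1 + 1/1.03 + 1/1.03^2
        r = 0.03
        disc = (1 + r) ** (-np.arange(3, dtype=float))
        assert disc.sum() == pytest.approx(1 + 1 / 1.03 + 1 / 1.03**2, abs=1e-12)

    def test_zero_discount_rate_recovers_undiscounted_sums(self, bundle):
        ev0 = Evaluator(bundle, discount_rate=0.0)
        base = ev0.run_baseline()
        # recompute HALYs by hand from the stream (already undiscounted)
        assert base.total_halys == pytest.approx(base.haly_stream.sum(),
                                                 abs=1e-9)
        ev3 = Evaluator(bundle, discount_rate=0.03)
        assert ev3.run_baseline().total_halys < base.total_halys


class TestMonotonicity:
    def test_beneficial_bmi_spec_gains_health_and_saves_costs(self, evaluator,
                                                              bundle):
        out = evaluator.evaluate(bundle.get_intervention("ssb_tax_20pct"))
        assert out.halys_gained > 0
        assert out.cost_offsets > 0

    def test_halys_gained_increase_with_effect_size(self, evaluator, bundle):
        spec = bundle.get_intervention("menu_kj_labelling")
        gains = [evaluator.evaluate(spec, overrides={"effect_size": e}).halys_gained
                 for e in (-5.0, -10.0, -20.0, -40.0)]
        assert np.all(np.diff(gains) > 0)

    def test_doubling_disability_weight_increases_halys_gained(self, evaluator,
                                                               bundle):
        spec = bundle.get_intervention("ssb_tax_20pct")
        base = evaluator.evaluate(spec)
        heavier = evaluator.evaluate(
            spec, overrides={"dw": {"type2_diabetes": 0.14}})
        assert heavier.halys_gained > base.halys_gained


class TestChildQualityTerm:
    def test_child_intervention_gains_include_hrql_term(self, bundle):
        spec = bundle.get_intervention("community_programs")
        with_term = evaluate_intervention(bundle, spec, child_hrql_coeff=0.005)
        without = evaluate_intervention(bundle, spec, child_hrql_coeff=0.0)
        assert with_term.halys_gained > without.halys_gained
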
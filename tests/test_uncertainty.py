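"""Monte Carlo propagation, univariate sensitivity, threshold analysis."""

import numpy as np
import pytest

from ace.uncertainty import (
    ParameterDistribution,
    default_distributions,
    run_monte_carlo,
    threshold_analysis,
    univariate_sensitivity,
)

SMALL = "school_activity_program"  # narrow target keeps runs fast


class TestDistributions:
    def test_unknown_family_rejected_before_any_run(self):
        with pytest.raises(ValueError, match="family"):
            ParameterDistribution("cost.scale", "triangular", {"mean": 1.0})

    def test_missing_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="log_se"):
            ParameterDistribution("rr.stroke.bmi", "lognormal", {"mean": 1.1})

    def test_families_sample_with_requested_moments(self):
        rng = np.random.default_rng(0)
        g = ParameterDistribution("cost.scale", "gamma",
                                  {"mean": 2.0, "se": 0.2}).sample(rng, 20000)
        assert g.mean() == pytest.approx(2.0, rel=0.02)
        assert g.std() == pytest.approx(0.2, rel=0.05)
        b = ParameterDistribution("intervention.uptake", "beta",
                                  {"mean": 0.3, "se": 0.05}).sample(rng, 20000)
        assert b.mean() == pytest.approx(0.3, rel=0.02)
        assert ((b > 0) & (b < 1)).all()


class TestMonteCarlo:
    def test_degenerate_distributions_collapse_to_deterministic(self, bundle,
                                                                evaluator):
        dists = [ParameterDistribution("intervention.effect_size",
                                       "degenerate", {"value": 100.0})]
        mc = run_monte_carlo(bundle, SMALL, dists=dists, n=3, seed=1,
                             evaluator=evaluator)
        h = mc.outputs["halys"]
        assert h["lo"] == pytest.approx(h["hi"])
        assert h["mean"] == pytest.approx(h["lo"])

    def test_same_seed_reproduces_identically(self, bundle, evaluator):
        a = run_monte_carlo(bundle, SMALL, n=5, seed=11, evaluator=evaluator)
        b = run_monte_carlo(bundle, SMALL, n=5, seed=11, evaluator=evaluator)
        assert a.outputs == b.outputs
        assert a.draws.equals(b.draws)  # NaN ICERs (dominant draws) compare equal
        c = run_monte_carlo(bundle, SMALL, n=5, seed=12, evaluator=evaluator)
        assert not np.allclose(a.draws["halys"], c.draws["halys"])

    def test_interval_covers_point_estimate(self, bundle, evaluator):
        mc = run_monte_carlo(bundle, SMALL, n=120, seed=5, evaluator=evaluator)
        h = mc.outputs["halys"]
        assert h["lo"] <= h["point"] <= h["hi"]
        assert h["lo"] < h["hi"]

    def test_n_below_one_rejected(self, bundle, evaluator):
        with pytest.raises(ValueError, match="n must"):
            run_monte_carlo(bundle, SMALL, n=0, evaluator=evaluator)

    def test_default_distribution_set_respects_pathway(self, bundle):
        met_spec = bundle.get_intervention("workplace_sedentary_program")
        kj_spec = bundle.get_intervention("menu_kj_labelling")
        met_paths = {d.path for d in default_distributions(bundle, met_spec)}
        kj_paths = {d.path for d in default_distributions(bundle, kj_spec)}
        assert any(p.endswith(".pa") for p in met_paths)
        assert not any(p.endswith(".pa") for p in kj_paths)


class TestUnivariateSensitivity:
    def test_base_value_reproduces_base_run(self, bundle, evaluator):
        spec = bundle.get_intervention(SMALL)
        table = univariate_sensitivity(bundle, spec, "cost.scale", [1.0],
                                       evaluator=evaluator)
        from ace.economics import cost_intervention
        base = evaluator.evaluate(spec)
        assert table.loc[0, "halys_gained"] == pytest.approx(base.halys_gained)
        assert table.loc[0, "intervention_cost"] == pytest.approx(
            cost_intervention(spec).total_discounted)

    def test_halys_strictly_decreasing_in_discount_rate(self, bundle,
                                                        evaluator):
        table = univariate_sensitivity(bundle, SMALL, "model.discount_rate",
                                       [0.0, 0.03, 0.05], evaluator=evaluator)
        assert np.all(np.diff(table["halys_gained"]) < 0)

    def test_empty_values_give_empty_table(self, bundle, evaluator):
        table = univariate_sensitivity(bundle, SMALL, "cost.scale", [],
                                       evaluator=evaluator)
        assert table.empty

    def test_out_of_range_value_rejected(self, bundle, evaluator):
        with pytest.raises(ValueError, match="uptake"):
            univariate_sensitivity(bundle, SMALL, "intervention.uptake",
                                   [1.5], evaluator=evaluator)


class TestThresholdAnalysis:
    def test_bisection_matches_algebraic_crossing(self, bundle, evaluator):
        # scaling every cost component makes the ICER affine in the scale:
        # icer(s) = (s*C0 - offsets)/halys, so the crossing has a closed form
        from ace.economics import cost_intervention
        spec = bundle.get_intervention(SMALL)
        out = evaluator.evaluate(spec)
        c0 = cost_intervention(spec).total_discounted
        wtp = 50_000.0
        s_star = (wtp * out.halys_gained + out.cost_offsets) / c0
        res = threshold_analysis(bundle, spec, "cost.scale",
                                 lo=0.0, hi=2.0 * s_star, wtp=wtp, tol=1e-6,
                                 evaluator=evaluator)
        assert res.threshold == pytest.approx(s_star, rel=1e-5)
        assert abs(res.icer_at_threshold - wtp) <= 1e-6 * wtp

    def test_dominant_across_bracket_reports_no_threshold(self, bundle,
                                                          evaluator):
        res = threshold_analysis(bundle, SMALL, "cost.scale",
                                 lo=0.0, hi=1.0, evaluator=evaluator)
        assert res.threshold is None
        assert "no threshold" in res.diagnostic

    def test_coarse_tolerance_converges_quickly(self, bundle, evaluator):
        from ace.economics import cost_intervention
        spec = bundle.get_intervention(SMALL)
        out = evaluator.evaluate(spec)
        c0 = cost_intervention(spec).total_discounted
        s_star = (50_000.0 * out.halys_gained + out.cost_offsets) / c0
        res = threshold_analysis(bundle, spec, "cost.scale",
                                 lo=0.0, hi=2.0 * s_star, tol=0.5,
                                 evaluator=evaluator)
        assert res.iterations < 10
        assert res.threshold is not None
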
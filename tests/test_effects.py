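"""Effect-size translation: unit conversions, maintenance profiles,
composition into per-stratum risk-factor deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ace.bundle import InterventionSpec
from ace.effects import (
    EnergyBalanceParams,
    build_risk_deltas,
    effect_at_time,
    kj_to_weight,
    met_to_kj_per_day,
    weight_to_bmi_delta,
    zscore_delta_to_bmi_delta,
)

PARAMS = EnergyBalanceParams()


@pytest.mark.parametrize("kj, group, expected", [
    (0.0, "adult", 0.0),
    (-94.0, "adult", -1.0),
    (-470.0, "adult", -5.0),
    (-100.0, "child", -1.0),
])
def test_kj_to_weight(kj, group, expected):
    assert kj_to_weight(kj, group, PARAMS) == pytest.approx(expected)


@pytest.mark.parametrize("kg, height, expected", [
    (0.0, 1.6, 0.0),
    (-1.0, 1.0, -1.0),
    (-2.5, 1.75, -2.5 / 3.0625),
])
def test_weight_to_bmi_delta(kg, height, expected):
    assert weight_to_bmi_delta(kg, height) == pytest.approx(expected)


def test_weight_to_bmi_rejects_nonpositive_height():
    with pytest.raises(ValueError, match="height"):
        weight_to_bmi_delta(-1.0, 0.0)


def _growth_ref(L):
    return pd.DataFrame([{"age": 10, "sex": "female", "L": L, "M": 16.0, "S": 0.1}])


class TestZScoreConversion:
    def test_zero_delta_is_zero(self):
        assert zscore_delta_to_bmi_delta(0.5, 0.0, 10, "female", _growth_ref(1.0)) == 0.0

    def test_linear_case_reduces_to_m_s_dz(self):
        # L=1 makes the LMS transform affine: delta = M*S*dz
        got = zscore_delta_to_bmi_delta(0.0, -0.25, 10, "female", _growth_ref(1.0))
        assert got == pytest.approx(16.0 * 0.1 * -0.25)

    def test_log_case_closed_form(self):
        got = zscore_delta_to_bmi_delta(0.0, -0.25, 10, "female", _growth_ref(0.0))
        assert got == pytest.approx(16.0 * (np.exp(-0.025) - 1.0))

    def test_adult_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            zscore_delta_to_bmi_delta(0.0, -0.25, 30, "female", _growth_ref(1.0))

    def test_monotone_in_delta_z(self):
        ref = _growth_ref(-1.0)
        vals = [zscore_delta_to_bmi_delta(0.0, dz, 10, "female", ref)
                for dz in np.linspace(-1, 1, 11)]
        assert np.all(np.diff(vals) > 0)


class TestMetConversion:
    def test_values(self):
        assert met_to_kj_per_day(0.0, 70.0, PARAMS) == 0.0
        assert met_to_kj_per_day(600.0, 70.0, PARAMS) == pytest.approx(
            600 * 70 * 0.0175 * 4.184 / 7)

    @given(st.floats(1.0, 3000.0), st.floats(20.0, 150.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_dose(self, met, mass):
        one = met_to_kj_per_day(met, mass, PARAMS)
        two = met_to_kj_per_day(2 * met, mass, PARAMS)
        assert two == pytest.approx(2 * one, rel=1e-12)


def _spec(**kw):
    base = dict(name="x", classification="program", target_age_lo=18,
                target_age_hi=100, target_sexes="both",
                effect_type="bmi_delta", effect_size=-0.5, effect_se=0.1,
                uptake=1.0, implementation_years=1,
                maintenance_type="sustained", maintenance_end_year=None)
    base.update(kw)
    return InterventionSpec(**base)


class TestEffectAtTime:
    def test_sustained_is_one_forever(self):
        assert effect_at_time(_spec(), 70) == 1.0

    def test_step_to_zero(self):
        s = _spec(maintenance_type="step_to_zero", maintenance_end_year=3,
                  implementation_years=3)
        assert effect_at_time(s, 2) == 1.0
        assert effect_at_time(s, 5) == 0.0

    def test_linear_decay_midpoint(self):
        s = _spec(maintenance_type="linear_decay", maintenance_end_year=11,
                  implementation_years=5)
        assert effect_at_time(s, 4) == 1.0
        assert effect_at_time(s, 8) == pytest.approx(0.5)
        assert effect_at_time(s, 11) == 0.0


class TestBuildRiskDeltas:
    def test_zero_uptake_gives_all_zero_deltas(self, bundle):
        d = build_risk_deltas(_spec(uptake=0.0), bundle.population,
                              bundle.growth_reference)
        assert not d.bmi_shift.any()
        assert not d.pa_moved.any()

    def test_bmi_delta_passes_through(self, bundle):
        d = build_risk_deltas(_spec(effect_size=-0.5), bundle.population,
                              bundle.growth_reference)
        adults = (bundle.population["age"] >= 18).to_numpy()
        assert np.allclose(d.bmi_shift[adults, :], -0.5)
        assert not d.bmi_shift[~adults, :].any()

    def test_kj_chain_matches_component_oracles(self, bundle):
        # -94 kJ/day at rho 94 is -1 kg; at height h the BMI shift is -1/h^2
        spec = _spec(effect_type="kj_per_day", effect_size=-94.0)
        d = build_risk_deltas(spec, bundle.population, bundle.growth_reference)
        pop = bundle.population
        i = pop.index[(pop["age"] == 40) & (pop["sex"] == "male")][0]
        h = pop.loc[i, "mean_height"]
        assert d.bmi_shift[i, 0] == pytest.approx(-1.0 / h**2)

    def test_child_z_effect_aimed_at_adults_rejected(self, bundle):
        spec = _spec(effect_type="bmi_z_delta", effect_size=-0.1,
                     target_age_lo=5, target_age_hi=30)
        with pytest.raises(ValueError, match="children"):
            build_risk_deltas(spec, bundle.population, bundle.growth_reference)

    def test_met_effect_without_bmi_pathway_when_disabled(self, bundle):
        spec = _spec(effect_type="met_min_per_week", effect_size=300.0)
        d = build_risk_deltas(spec, bundle.population, bundle.growth_reference,
                              pa_affects_bmi=False)
        assert not d.bmi_shift.any()
        assert d.pa_moved[0] == pytest.approx(spec.uptake)

    def test_beneficial_effects_never_increase_bmi(self, bundle):
        for spec in (_spec(effect_type="kj_per_day", effect_size=-30.0),
                     _spec(effect_type="met_min_per_week", effect_size=300.0),
                     _spec(effect_size=-0.5)):
            d = build_risk_deltas(spec, bundle.population,
                                  bundle.growth_reference)
            assert (d.bmi_shift <= 0).all()

    @given(st.floats(0.1, 3.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_effect_size(self, factor):
        b = _BUNDLE
        base = build_risk_deltas(_spec(effect_type="kj_per_day",
                                       effect_size=-20.0),
                                 b.population, b.growth_reference)
        scaled = build_risk_deltas(_spec(effect_type="kj_per_day",
                                         effect_size=-20.0 * factor),
                                   b.population, b.growth_reference)
        np.testing.assert_allclose(scaled.bmi_shift, base.bmi_shift * factor,
                                   rtol=1e-12, atol=1e-15)

    def test_expired_years_are_exactly_zero(self, bundle):
        spec = _spec(maintenance_type="step_to_zero", maintenance_end_year=3,
                     implementation_years=3)
        d = build_risk_deltas(spec, bundle.population, bundle.growth_reference)
        assert not d.bmi_shift[:, 3:].any()
        assert d.bmi_shift[:, :3].any()


# hypothesis-driven test cannot take a function-scoped fixture: build once
import ace as _ace  # noqa: E402

_BUNDLE = _ace.generate_bundle(seed=2)
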
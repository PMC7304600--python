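"""Synthetic epidemiology generator.

Produces internally consistent population, disease, relative-risk, growth
reference and intervention bundles with the statistical structure the
multi-state life table model assumes: an age (2-100) x sex population with
per-stratum log-normal BMI distributions and four ordered physical-activity
bands, a nine-disease catalogue (all BMI-related, five also
physical-activity-related), log-linear BMI relative risks, categorical PA
relative risks, an LMS growth reference for children, and sixteen
intervention templates mixing regulatory and program-based designs.

Everything is deterministic for a fixed seed.  The defaults are the study
conditions; they are not fitted to any real population.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .bundle import (
    AGE_MAX,
    AGE_MIN,
    Bundle,
    BundleValidationError,
    DISEASE_IDS,
    PA_DISEASES,
    SEXES,
    steady_state_prevalence,
)

# ---------------------------------------------------------------------------
# default configuration (overridable via a YAML mapping with the same keys)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "population": {
        # cross-sectional mean BMI trajectory (kg/m^2) and coefficient of
        # variation; child values ramp into the adult curve at 18
        "bmi_mean_child_at_2": 16.0,
        "bmi_mean_at_18": 24.0,
        "bmi_mean_at_60": 28.5,
        "bmi_decline_per_year_after_60": 0.02,
        "bmi_cv": 0.17,
        "bmi_mu_jitter_sd": 0.004,  # seeded log-scale jitter per stratum
        # Gompertz background (non-modelled-disease) mortality
        "gompertz_a": 2.2e-5,
        "gompertz_b": 0.095,
        "background_floor": 1.5e-4,
        "male_mortality_factor": 1.25,
        # all-cause morbidity (YLD rate)
        "yld_at_2": 0.04,
        "yld_slope_per_year": 0.0012,
        "yld_cap": 0.35,
        # adult PA band prevalence at age 18 (inactive, low, moderate, high)
        "pa_base": (0.20, 0.35, 0.28, 0.17),
        "pa_inactive_drift_per_year": 0.004,
        "adult_height": {"female": 1.63, "male": 1.78},
        "height_at_2": 0.88,
        "count_at_young": 290000.0,
        "count_decay_age": 60,
        "count_decay_rate": 0.045,
    },
    "growth_reference": {
        # LMS skewness parameter; M tracks just below the population mean so
        # that mean child BMI sits above the reference median
        "L": -1.0,
        "S": 0.11,
        "m_ratio": 0.965,
    },
    "energy_balance": {
        "rho_adult": 94.0,   # kJ/day of intake change per kg steady-state weight change
        "rho_child": 100.0,
        "met_kcal_coeff": 0.0175,  # kcal per kg per MET-minute
        "kj_per_kcal": 4.184,
        "net_mets": False,
    },
    "flags": {
        "pa_affects_bmi": True,
        "child_hrql_coeff": 0.005,  # utility decrement per BMI unit above reference, ages 2-17
    },
    # disease_id: (onset_age, incidence_at_50, log-slope/yr, case_fatality,
    #              disability_weight, annual_cost_per_case, sex_restriction)
    "diseases": {
        "kidney_cancer":              (30, 1.5e-4, 0.045, 0.080, 0.25, 18000.0, None),
        "colorectal_cancer":          (30, 4.0e-4, 0.055, 0.070, 0.22, 20000.0, None),
        "endometrial_cancer":         (35, 1.8e-4, 0.040, 0.040, 0.20, 15000.0, "female"),
        "breast_cancer":              (25, 1.2e-3, 0.020, 0.030, 0.18, 16000.0, "female"),
        "type2_diabetes":             (20, 4.0e-3, 0.035, 0.006, 0.07,  4000.0, None),
        "hypertensive_heart_disease": (40, 3.0e-4, 0.060, 0.030, 0.09,  6000.0, None),
        "ischaemic_heart_disease":    (30, 2.5e-3, 0.055, 0.040, 0.08,  9000.0, None),
        "stroke":                     (30, 1.2e-3, 0.065, 0.060, 0.26, 11000.0, None),
        "osteoarthritis":             (30, 3.5e-3, 0.030, 0.000, 0.10,  2500.0, None),
    },
    "incidence_cap": 0.06,
    "incidence_jitter_sd": 0.05,  # seeded log-scale jitter per disease
    # per-BMI-unit relative risks above TMREL and categorical PA relative
    # risks (inactive, low, moderate, high; most-active band is reference)
    "rr_bmi": {
        "kidney_cancer": 1.06, "colorectal_cancer": 1.05,
        "endometrial_cancer": 1.10, "breast_cancer": 1.04,
        "type2_diabetes": 1.12, "hypertensive_heart_disease": 1.08,
        "ischaemic_heart_disease": 1.06, "stroke": 1.07,
        "osteoarthritis": 1.03,
    },
    "rr_bmi_log_se": 0.02,
    "rr_pa": {
        "colorectal_cancer":       (1.35, 1.22, 1.10, 1.0),
        "breast_cancer":           (1.25, 1.15, 1.07, 1.0),
        "type2_diabetes":          (1.45, 1.28, 1.12, 1.0),
        "ischaemic_heart_disease": (1.50, 1.30, 1.14, 1.0),
        "stroke":                  (1.40, 1.25, 1.10, 1.0),
    },
    "rr_pa_log_se": 0.05,
    "tmrel": 21.0,
}


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merge ``overrides`` into a copy of the default configuration."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def _check_positive(value, name):
    if not np.all(np.asarray(value) > 0):
        raise BundleValidationError(f"config.{name}: must be > 0")


# ---------------------------------------------------------------------------
# population

def generate_population(config: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the 99-age x 2-sex population table.

    Deterministic for a fixed seed; different seeds perturb the per-stratum
    BMI location parameters.  The all-cause mortality column is constructed
    as Gompertz background mortality plus the mortality implied by the
    disease catalogue at steady state, so the mortality envelope invariant
    holds by construction (see :func:`generate_bundle`; this function alone
    fills in background mortality only).
    """
    cfg = config if config is not None else make_config()
    p = cfg["population"]
    _check_positive(p["bmi_cv"], "population.bmi_cv")
    _check_positive(p["adult_height"]["female"], "population.adult_height")
    if not (0 < p["yld_cap"] < 1):
        raise BundleValidationError("config.population.yld_cap: must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    rows = []
    for sex in SEXES:
        mean_bmi = _mean_bmi_curve(ages, p)
        jitter = rng.normal(0.0, p["bmi_mu_jitter_sd"], size=len(ages))
        cv = p["bmi_cv"]
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = np.log(mean_bmi) - 0.5 * sigma**2 + jitter
        if sigma <= 0:
            raise BundleValidationError("population.bmi_sigma: must be > 0")

        heights = _height_curve(ages, sex, p)
        mort = (
            p["gompertz_a"] * np.exp(p["gompertz_b"] * ages)
            + p["background_floor"]
        )
        if sex == "male":
            mort = mort * p["male_mortality_factor"]
        yld = np.minimum(p["yld_at_2"] + p["yld_slope_per_year"] * (ages - AGE_MIN),
                         p["yld_cap"])

        pa = _pa_curve(ages, p, rng)
        count = p["count_at_young"] * np.exp(
            -np.maximum(0, ages - p["count_decay_age"]) * p["count_decay_rate"]
        )
        if sex == "male":
            count = count * 1.01

        for i, a in enumerate(ages):
            rows.append({
                "age": int(a), "sex": sex, "count": float(np.round(count[i])),
                "bmi_mu": float(mu[i]), "bmi_sigma": float(sigma),
                "pa_inactive": pa[i, 0], "pa_low": pa[i, 1],
                "pa_moderate": pa[i, 2], "pa_high": pa[i, 3],
                "mean_height": float(heights[i]),
                "mortality_all_cause": float(mort[i]),
                "yld_all_cause": float(yld[i]),
            })
    return pd.DataFrame(rows)


def _mean_bmi_curve(ages, p):
    child = p["bmi_mean_child_at_2"] + (ages - 2) * (
        (p["bmi_mean_at_18"] - p["bmi_mean_child_at_2"]) / 16.0
    )
    adult = p["bmi_mean_at_18"] + np.minimum(ages - 18, 42) * (
        (p["bmi_mean_at_60"] - p["bmi_mean_at_18"]) / 42.0
    )
    adult = adult - np.maximum(0, ages - 60) * p["bmi_decline_per_year_after_60"]
    return np.where(ages < 18, child, adult)


def _height_curve(ages, sex, p):
    adult = p["adult_height"][sex]
    h2 = p["height_at_2"]
    grow = h2 + (np.minimum(ages, 18) - 2) * (adult - h2) / 16.0
    return np.where(ages < 18, grow, adult - np.maximum(0, ages - 60) * 0.0005)


def _pa_curve(ages, p, rng):
    base = np.asarray(p["pa_base"], dtype=float)
    out = np.empty((len(ages), 4))
    for i, a in enumerate(ages):
        v = base.copy()
        if a >= 18:
            drift = p["pa_inactive_drift_per_year"] * (a - 18)
            v[0] += drift
        else:
            v = np.array([0.12, 0.28, 0.32, 0.28])  # children more active
        v = v + rng.uniform(0, 1e-3, size=4)  # seeded jitter, then renormalise
        out[i] = v / v.sum()
    return out


# ---------------------------------------------------------------------------
# disease catalogue and relative risks

def generate_disease_catalogue(config: dict | None = None, seed: int = 0
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the nine-disease rate table and the relative-risk table.

    Incidence follows an exponential age ramp above a disease-specific
    onset age; case fatality and disability weight are age-constant; the
    steady-state prevalence implied by the process stays below 0.5 at every
    age for the default parameters.
    """
    cfg = config if config is not None else make_config()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    rows = []
    for did in DISEASE_IDS:
        onset, i50, slope, cf, dw, cost, restrict = cfg["diseases"][did]
        jit = float(np.exp(rng.normal(0.0, cfg["incidence_jitter_sd"])))
        for sex in SEXES:
            blocked = restrict is not None and sex != restrict
            inc = np.where(
                ages >= onset,
                np.minimum(i50 * jit * np.exp(slope * (ages - 50)), cfg["incidence_cap"]),
                0.0,
            )
            if blocked:
                inc = np.zeros_like(inc)
            for i, a in enumerate(ages):
                rows.append({
                    "disease_id": did, "age": int(a), "sex": sex,
                    "incidence": float(inc[i]), "case_fatality": float(cf),
                    "remission": 0.0, "disability_weight": float(dw),
                    "annual_cost_per_case": float(cost),
                    "bmi_related": True, "pa_related": did in PA_DISEASES,
                    "sex_restriction": restrict if restrict is not None else "",
                })
    diseases = pd.DataFrame(rows)

    rr_rows = []
    for did in DISEASE_IDS:
        rr_rows.append({
            "disease_id": did, "risk_factor": "bmi", "form": "loglinear_per_unit",
            "rr_per_unit": float(cfg["rr_bmi"][did]),
            "rr_inactive": np.nan, "rr_low": np.nan,
            "rr_moderate": np.nan, "rr_high": np.nan,
            "log_se": float(cfg["rr_bmi_log_se"]), "tmrel": float(cfg["tmrel"]),
        })
    for did, vec in cfg["rr_pa"].items():
        rr_rows.append({
            "disease_id": did, "risk_factor": "pa", "form": "categorical",
            "rr_per_unit": np.nan,
            "rr_inactive": float(vec[0]), "rr_low": float(vec[1]),
            "rr_moderate": float(vec[2]), "rr_high": float(vec[3]),
            "log_se": float(cfg["rr_pa_log_se"]), "tmrel": float(cfg["tmrel"]),
        })
    return diseases, pd.DataFrame(rr_rows)


def generate_growth_reference(config: dict | None = None) -> pd.DataFrame:
    """LMS parameters for ages 2-17 by sex.  M tracks just below the
    cross-sectional mean BMI so the child population carries positive BMI
    excess relative to the reference median."""
    cfg = config if config is not None else make_config()
    g = cfg["growth_reference"]
    _check_positive(g["S"], "growth_reference.S")
    _check_positive(g["m_ratio"], "growth_reference.m_ratio")
    ages = np.arange(AGE_MIN, 18)
    rows = []
    for sex in SEXES:
        mean_bmi = _mean_bmi_curve(ages, cfg["population"])
        for i, a in enumerate(ages):
            rows.append({
                "age": int(a), "sex": sex,
                "L": float(g["L"]),
                "M": float(mean_bmi[i] * g["m_ratio"]),
                "S": float(g["S"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interventions

def _mk_costs(*comps):
    return [
        {
            "label": label, "sector": sector, "amount": amount,
            "year_first": y0, "year_last": y1,
            "health_related": health, "time_cost": time_cost,
            "source_year": 2010,
        }
        for (label, sector, amount, y0, y1, health, time_cost) in comps
    ]


#: Sixteen intervention templates: 9 regulatory, 7 program-based, four
#: targeting children, two sedentary-behaviour types.  Effect sizes, uptake
#: and costs are synthetic round numbers on realistic scales.
DEFAULT_INTERVENTION_TEMPLATES: list[dict] = [
    dict(name="alcohol_volumetric_tax", classification="regulatory",
         target_age_lo=14, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-35.0, effect_se=7.0,
         uptake=0.80, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 5.0e6, 0, 0, False, False),
                         ("administration", "federal_govt", 2.0e6, 0, 98, False, False),
                         ("industry_compliance", "industry", 3.0e6, 0, 2, False, False))),
    dict(name="community_programs", classification="program",
         target_age_lo=5, target_age_hi=17, target_sexes="both",
         effect_type="bmi_z_delta", effect_size=-0.10, effect_se=0.03,
         uptake=0.60, implementation_years=3, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("program_delivery", "state_govt", 2.6e8, 0, 2, True, False))),
    dict(name="insurer_weight_loss_incentives", classification="program",
         target_age_lo=18, target_age_hi=100, target_sexes="both",
         effect_type="bmi_delta", effect_size=-0.60, effect_se=0.15,
         uptake=0.08, implementation_years=5, maintenance_type="linear_decay",
         maintenance_end_year=11,
         costs=_mk_costs(("incentive_payments", "industry", 5.0e8, 0, 2, True, False),
                         ("program_running", "industry", 4.0e7, 3, 4, True, False))),
    dict(name="fuel_excise_increase", classification="regulatory",
         target_age_lo=18, target_age_hi=64, target_sexes="both",
         effect_type="met_min_per_week", effect_size=8.0, effect_se=3.0,
         uptake=0.35, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 4.0e6, 0, 0, False, False))),
    dict(name="menu_kj_labelling", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-12.0, effect_se=4.0,
         uptake=0.50, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 5.0e6, 0, 0, False, False),
                         ("education_campaign", "federal_govt", 1.1e7, 0, 2, True, False),
                         ("menu_reprinting", "industry", 5.0e6, 0, 9, False, False))),
    dict(name="ssb_mass_media", classification="program",
         target_age_lo=18, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-20.0, effect_se=6.0,
         uptake=0.40, implementation_years=3, maintenance_type="step_to_zero",
         maintenance_end_year=3,
         costs=_mk_costs(("media_buy", "federal_govt", 1.03e7, 0, 2, True, False))),
    dict(name="ssb_package_size_cap", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-16.0, effect_se=5.0,
         uptake=0.45, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 5.0e6, 0, 0, False, False),
                         ("production_change", "industry", 4.6e7, 0, 2, False, False),
                         ("compliance", "federal_govt", 1.0e6, 0, 98, False, False))),
    dict(name="hsr_reformulation", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-4.0, effect_se=1.5,
         uptake=0.55, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("scheme_administration", "federal_govt", 1.0e7, 0, 2, False, False),
                         ("reformulation", "industry", 1.0e7, 0, 2, False, False),
                         ("maintenance", "federal_govt", 1.0e6, 3, 98, False, False))),
    dict(name="ssb_sugar_reformulation", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-9.0, effect_se=3.0,
         uptake=0.50, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("target_setting", "federal_govt", 1.0e6, 0, 0, False, False),
                         ("reformulation", "industry", 1.0e7, 0, 2, False, False),
                         ("monitoring", "federal_govt", 5.0e5, 0, 98, False, False))),
    dict(name="tv_advertising_restrictions", classification="regulatory",
         target_age_lo=5, target_age_hi=15, target_sexes="both",
         effect_type="kj_per_day", effect_size=-25.0, effect_se=8.0,
         uptake=0.70, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 5.0e6, 0, 0, False, False),
                         ("compliance_monitoring", "federal_govt", 5.0e5, 0, 98, False, False))),
    dict(name="ssb_price_promotion_restrictions", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-10.0, effect_se=4.0,
         uptake=0.50, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 5.0e6, 0, 0, False, False),
                         ("retail_compliance", "industry", 4.0e6, 0, 2, False, False),
                         ("monitoring", "state_govt", 5.0e5, 0, 98, False, False))),
    dict(name="school_sedentary_program", classification="program",
         target_age_lo=8, target_age_hi=9, target_sexes="both",
         effect_type="met_min_per_week", effect_size=90.0, effect_se=30.0,
         uptake=0.70, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("teacher_delivery", "state_govt", 4.7e6, 0, 2, True, False),
                         ("materials", "state_govt", 3.0e5, 0, 2, False, False))),
    dict(name="school_activity_program", classification="program",
         target_age_lo=8, target_age_hi=9, target_sexes="both",
         effect_type="met_min_per_week", effect_size=100.0, effect_se=35.0,
         uptake=0.70, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("teacher_delivery", "state_govt", 3.0e6, 0, 2, True, False),
                         ("play_equipment", "state_govt", 3.0e5, 0, 2, False, False))),
    dict(name="ssb_tax_20pct", classification="regulatory",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-30.0, effect_se=9.0,
         uptake=0.55, implementation_years=99, maintenance_type="sustained",
         maintenance_end_year=None,
         costs=_mk_costs(("legislation", "federal_govt", 4.0e6, 0, 0, False, False),
                         ("tax_administration", "federal_govt", 4.0e6, 0, 98, False, False))),
    dict(name="supermarket_shelf_tags", classification="program",
         target_age_lo=2, target_age_hi=100, target_sexes="both",
         effect_type="kj_per_day", effect_size=-5.0, effect_se=2.0,
         uptake=0.30, implementation_years=3, maintenance_type="step_to_zero",
         maintenance_end_year=3,
         costs=_mk_costs(("tag_installation", "industry", 3.0e6, 0, 2, False, False))),
    dict(name="workplace_sedentary_program", classification="program",
         target_age_lo=18, target_age_hi=65, target_sexes="both",
         effect_type="met_min_per_week", effect_size=60.0, effect_se=15.0,
         uptake=0.20, implementation_years=1, maintenance_type="linear_decay",
         maintenance_end_year=5,
         costs=_mk_costs(("standing_desks", "industry", 8.0e7, 0, 0, False, False),
                         ("health_coaching", "industry", 1.0e7, 0, 0, True, False))),
]


def generate_interventions(config: dict | None = None, seed: int = 0,
                           templates: list[dict] | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialise intervention specs and their cost components.

    The bundled default emits 16 specs (9 regulatory, 7 program-based).
    Template fields are validated through the InterventionSpec invariants,
    so e.g. an uptake outside [0, 1] or an unknown effect type is rejected
    with a message naming the field.
    """
    templates = templates if templates is not None else DEFAULT_INTERVENTION_TEMPLATES
    if not templates:
        raise BundleValidationError("interventions: at least one template required")
    spec_rows, cost_rows = [], []
    for t in templates:
        t = dict(t)
        costs = t.pop("costs", [])
        # dataclass construction enforces the invariants
        from .bundle import CostComponent, InterventionSpec
        spec = InterventionSpec(
            cost_components=tuple(
                CostComponent(
                    label=c["label"], sector=c["sector"], amount=c["amount"],
                    year_first=c["year_first"], year_last=c["year_last"],
                    health_related=c["health_related"], time_cost=c["time_cost"],
                    source_year=c.get("source_year", 2010),
                )
                for c in costs
            ),
            **t,
        )
        spec_rows.append({
            "name": spec.name, "classification": spec.classification,
            "target_age_lo": spec.target_age_lo, "target_age_hi": spec.target_age_hi,
            "target_sexes": spec.target_sexes, "effect_type": spec.effect_type,
            "effect_size": spec.effect_size, "effect_se": spec.effect_se,
            "uptake": spec.uptake,
            "implementation_years": spec.implementation_years,
            "maintenance_type": spec.maintenance_type,
            "maintenance_end_year": (np.nan if spec.maintenance_end_year is None
                                     else spec.maintenance_end_year),
        })
        for c in spec.cost_components:
            cost_rows.append({
                "intervention": spec.name, "label": c.label, "sector": c.sector,
                "amount": c.amount, "year_first": c.year_first,
                "year_last": c.year_last, "health_related": c.health_related,
                "time_cost": c.time_cost, "source_year": c.source_year,
            })
    return pd.DataFrame(spec_rows), pd.DataFrame(cost_rows)


# ---------------------------------------------------------------------------
# full bundle

def generate_bundle(config: dict | None = None, seed: int = 0) -> Bundle:
    """Generate a complete, mutually consistent bundle.

    All-cause mortality is assembled as background (Gompertz) mortality plus
    the disease-implied mortality at steady state, which guarantees the
    mortality envelope invariant and leaves a non-negative residual at every
    age.
    """
    cfg = config if config is not None else make_config()
    pop = generate_population(cfg, seed=seed)
    diseases, rr = generate_disease_catalogue(cfg, seed=seed)
    growth = generate_growth_reference(cfg)
    interventions, cost_components = generate_interventions(cfg, seed=seed)

    implied = _implied_mortality_frame(diseases)
    pop = pop.merge(implied, on=["age", "sex"], how="left")
    pop["mortality_all_cause"] = (
        pop["mortality_all_cause"] + pop["implied_mortality"].fillna(0.0)
    )
    pop = pop.drop(columns=["implied_mortality"])

    return Bundle(
        population=pop, diseases=diseases, rr=rr, growth_reference=growth,
        interventions=interventions, cost_components=cost_components,
    )


def _implied_mortality_frame(diseases: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (did, sex), grp in diseases.groupby(["disease_id", "sex"]):
        grp = grp.sort_values("age")
        p = steady_state_prevalence(
            grp["incidence"].to_numpy(),
            grp["case_fatality"].to_numpy(),
            grp["remission"].to_numpy(),
        )
        out.append(pd.DataFrame({
            "age": grp["age"].to_numpy(), "sex": sex,
            "implied": p * grp["case_fatality"].to_numpy(),
        }))
    df = pd.concat(out, ignore_index=True)
    return (
        df.groupby(["age", "sex"], as_index=False)["implied"].sum()
        .rename(columns={"implied": "implied_mortality"})
    )
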
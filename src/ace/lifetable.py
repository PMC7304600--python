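"""Proportional multi-state life table (PMSLT) Markov cohort engine.

Every age (2-100) x sex stratum of the 2010 population is followed as a
closed cohort in annual cycles until age 100.  For each of the nine
diseases a sub-lifetable tracks the susceptible (S) and prevalent (C)
proportions; intervention scenarios scale disease incidence by (1 - PIF).
The prevalence proportion p = C/(S+C) feeds back into the main lifetable:

* all-cause mortality  m = residual + sum_d p_d * case_fatality_d,
  where residual is baseline all-cause mortality net of the disease-implied
  part (floored at zero);
* morbidity            yld = baseline YLD + sum_d (p_d - p_d,baseline) * dw_d
  + a childhood BMI quality term, capped to [0, 1);
* person-years use the half-cycle correction L = (l_y + l_{y+1})/2, and
  health-adjusted life years (HALYs) are L * (1 - yld) discounted at rate r
  with year 0 (2010) undiscounted;
* healthcare costs count the nine modelled diseases only:
  sum_d p_d * L * cost_d, discounted identically.

Within a cycle the update order is fixed: incidence, case fatality,
remission; rates are converted to probabilities via q = 1 - exp(-rate).
Background mortality, removed proportionally from S and C, cancels in
p = C/(S+C) and is therefore handled entirely in the main lifetable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import AGE_MIN, AGE_MAX, Bundle, DISEASE_IDS, InterventionSpec, SEXES
from .effects import (
    EnergyBalanceParams,
    RiskDeltas,
    build_risk_deltas,
)
from .pif import PifCalculator, pifs_for_intervention

N_YEARS = AGE_MAX - AGE_MIN + 1  # 99 annual cycles covers every cohort


@dataclass
class DiseaseTrajectory:
    """Per-year compartments of one disease process."""

    S: np.ndarray          # disease-free proportion at the start of each year
    C: np.ndarray          # prevalent proportion at the start of each year
    d_mort: np.ndarray     # annual disease mortality of the cohort (C*f)
    new_cases: np.ndarray  # incident proportion during each year


@dataclass
class ScenarioOutcome:
    """Aggregate discounted outcomes of one scenario run."""

    label: str
    total_halys: float
    total_cost: float
    haly_stream: np.ndarray  # by model year, summed over cohorts
    cost_stream: np.ndarray


@dataclass
class EvaluationOutput:
    halys_gained: float
    cost_offsets: float  # baseline cost - scenario cost; positive = savings
    baseline: ScenarioOutcome
    scenario: ScenarioOutcome
    haly_stream: np.ndarray = field(default_factory=lambda: np.zeros(0))
    offset_stream: np.ndarray = field(default_factory=lambda: np.zeros(0))


def run_disease_process(incidence, case_fatality, remission,
                        incidence_scale=None, S0: float = 1.0, C0: float = 0.0,
                        convert_rates: bool = True) -> DiseaseTrajectory:
    """Reference single-cohort disease process.

    ``incidence``, ``case_fatality`` and ``remission`` are annual rates per
    year (arrays of equal length); ``incidence_scale`` holds the per-year
    (1 - PIF) factors.  With ``convert_rates`` the rates become
    probabilities via q = 1 - exp(-rate), which keeps compartments
    non-negative; the raw small-rate mode applies rates directly and raises
    if a compartment would go negative.
    """
    incidence = np.asarray(incidence, dtype=float)
    case_fatality = np.asarray(case_fatality, dtype=float)
    remission = np.asarray(remission, dtype=float)
    n = len(incidence)
    scale = np.ones(n) if incidence_scale is None else np.asarray(incidence_scale, float)

    S = np.empty(n + 1)
    C = np.empty(n + 1)
    d_mort = np.empty(n)
    new_cases = np.empty(n)
    S[0], C[0] = S0, C0
    for y in range(n):
        i_eff = incidence[y] * scale[y]
        if convert_rates:
            qi = 1.0 - np.exp(-i_eff)
            qf = 1.0 - np.exp(-case_fatality[y])
            qr = 1.0 - np.exp(-remission[y])
        else:
            qi, qf, qr = i_eff, case_fatality[y], remission[y]
        new = S[y] * qi
        deaths = C[y] * qf
        rem = C[y] * qr
        S[y + 1] = S[y] - new + rem
        C[y + 1] = C[y] + new - deaths - rem
        if S[y + 1] < -1e-12 or C[y + 1] < -1e-12:
            raise ValueError(
                f"disease process went negative at year {y}: rate too large "
                "for raw small-rate mode"
            )
        d_mort[y] = deaths
        new_cases[y] = new
    return DiseaseTrajectory(S=S, C=C, d_mort=d_mort, new_cases=new_cases)


def _canonical_population(population: pd.DataFrame) -> pd.DataFrame:
    order = {s: i for i, s in enumerate(SEXES)}
    pop = population.copy()
    pop["_sex_order"] = pop["sex"].map(order)
    pop = pop.sort_values(["_sex_order", "age"]).drop(columns="_sex_order")
    return pop.reset_index(drop=True)


class Evaluator:
    """Builds the model arrays once per bundle and evaluates interventions.

    Rate tables are gathered by attained age ahead of time, so scenario
    runs reduce to a single 99-cycle vectorised loop over
    [cohort x disease] arrays; Monte Carlo iterations reuse everything
    except the sampled parameters.
    """

    def __init__(self, bundle: Bundle, discount_rate: float = 0.03,
                 child_hrql_coeff: float = 0.005,
                 energy_params: EnergyBalanceParams | None = None,
                 pa_affects_bmi: bool = True, pif_nodes: int = 2001):
        self.bundle = bundle
        self.discount_rate = discount_rate
        self.child_hrql_coeff = child_hrql_coeff
        self.energy_params = energy_params or EnergyBalanceParams()
        self.pa_affects_bmi = pa_affects_bmi

        pop = _canonical_population(bundle.population)
        self.population = pop
        n_s = len(pop)
        self.n_s = n_s
        self.count = pop["count"].to_numpy()
        self.age0 = pop["age"].to_numpy().astype(int)
        self.sex = pop["sex"].to_numpy()

        self.pif_calc = PifCalculator(pop, bundle.rr, n_nodes=pif_nodes)
        meta = bundle.diseases.groupby("disease_id").first()
        self._pa_related = frozenset(meta.index[meta["pa_related"].astype(bool)])

        # per (sex, age) lookup tables
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        self._age_index = {a: i for i, a in enumerate(ages)}
        by_sex = {s: pop[pop["sex"] == s].set_index("age") for s in SEXES}

        n_d = len(DISEASE_IDS)
        dis = bundle.diseases
        inc = np.zeros((n_d, 2, len(ages)))
        cf = np.zeros_like(inc)
        rem = np.zeros_like(inc)
        self.dw = np.zeros(n_d)
        self.cost_per_case = np.zeros(n_d)
        for d_idx, did in enumerate(DISEASE_IDS):
            sub = dis[dis["disease_id"] == did]
            self.dw[d_idx] = float(sub["disability_weight"].iloc[0])
            self.cost_per_case[d_idx] = float(sub["annual_cost_per_case"].iloc[0])
            for s_idx, sex in enumerate(SEXES):
                g = sub[sub["sex"] == sex].sort_values("age")
                inc[d_idx, s_idx] = g["incidence"].to_numpy()
                cf[d_idx, s_idx] = g["case_fatality"].to_numpy()
                rem[d_idx, s_idx] = g["remission"].to_numpy()

        # steady-state compartments by age (start-of-age values)
        S_ss = np.ones((n_d, 2, len(ages)))
        C_ss = np.zeros_like(S_ss)
        for d in range(n_d):
            for s in range(2):
                qi = 1.0 - np.exp(-inc[d, s])
                qf = 1.0 - np.exp(-cf[d, s])
                qr = 1.0 - np.exp(-rem[d, s])
                for a in range(1, len(ages)):
                    new = S_ss[d, s, a - 1] * qi[a - 1]
                    dth = C_ss[d, s, a - 1] * qf[a - 1]
                    rm = C_ss[d, s, a - 1] * qr[a - 1]
                    S_ss[d, s, a] = S_ss[d, s, a - 1] - new + rm
                    C_ss[d, s, a] = C_ss[d, s, a - 1] + new - dth - rm
        tot = S_ss + C_ss
        p_ss = np.where(tot > 0, C_ss / tot, 0.0)

        # residual (non-modelled) mortality by sex and age
        mort_all = np.zeros((2, len(ages)))
        yld_all = np.zeros((2, len(ages)))
        mean_bmi = np.zeros((2, len(ages)))
        for s_idx, sex in enumerate(SEXES):
            t = by_sex[sex]
            mort_all[s_idx] = t["mortality_all_cause"].reindex(ages).to_numpy()
            yld_all[s_idx] = t["yld_all_cause"].reindex(ages).to_numpy()
            mean_bmi[s_idx] = np.exp(t["bmi_mu"].reindex(ages).to_numpy()
                                     + 0.5 * t["bmi_sigma"].reindex(ages).to_numpy() ** 2)
        implied = (p_ss * cf).sum(axis=0)
        residual = mort_all - implied
        if (residual < -1e-12).any():
            warnings.warn("residual mortality floored at 0 for some ages",
                          RuntimeWarning, stacklevel=2)
        residual = np.maximum(residual, 0.0)

        # child BMI reference (growth-chart median), by sex and age
        ref = np.full((2, len(ages)), np.inf)  # inf disables the term for adults
        gr = bundle.growth_reference
        for s_idx, sex in enumerate(SEXES):
            sub = gr[gr["sex"] == sex]
            for _, r in sub.iterrows():
                ref[s_idx, self._age_index[int(r["age"])]] = float(r["M"])

        # gather by attained age: [*, cohort, year]; years past age 100 inert
        sex_idx = np.array([0 if s == "female" else 1 for s in self.sex])
        a0_idx = np.array([self._age_index[a] for a in self.age0])
        att = a0_idx[:, None] + np.arange(N_YEARS)[None, :]
        self.active = att <= len(ages) - 1  # [n_s, N_YEARS]
        att_c = np.minimum(att, len(ages) - 1)

        sx = sex_idx[:, None]
        self.inc_g = inc[:, sx, att_c]            # [n_d, n_s, n_y]
        self.qf_g = 1.0 - np.exp(-cf[:, sx, att_c])
        self.qr_g = 1.0 - np.exp(-rem[:, sx, att_c])
        self.cf_g = cf[:, sx, att_c]
        self.p_base = p_ss[:, sx, att_c]
        self.residual_g = residual[sex_idx[:, None], att_c]
        self.yld_g = yld_all[sex_idx[:, None], att_c]
        self.mean_bmi_g = mean_bmi[sex_idx[:, None], att_c]
        self.child_ref_g = ref[sex_idx[:, None], att_c]
        self.S0 = S_ss[:, sex_idx, a0_idx]
        self.C0 = C_ss[:, sex_idx, a0_idx]

    # ------------------------------------------------------------------
    def _disease_compartments(self, incidence_scale: np.ndarray | None
                              ) -> np.ndarray:
        """Prevalence proportion p[d, cohort, year] at the start of each
        year under per-year incidence scaling."""
        n_d = len(DISEASE_IDS)
        S = self.S0.copy()
        C = self.C0.copy()
        p = np.zeros((n_d, self.n_s, N_YEARS))
        for y in range(N_YEARS):
            tot = S + C
            p[:, :, y] = np.where(tot > 0, C / tot, 0.0)
            inc = self.inc_g[:, :, y]
            if incidence_scale is not None:
                inc = inc * incidence_scale[:, :, y]
            qi = 1.0 - np.exp(-inc)
            new = S * qi
            deaths = C * self.qf_g[:, :, y]
            rm = C * self.qr_g[:, :, y]
            S = S - new + rm
            C = C + new - deaths - rm
        return p

    def _aggregate(self, p: np.ndarray, label: str,
                   child_yld_delta: np.ndarray | None = None,
                   dw: np.ndarray | None = None,
                   cost_per_case: np.ndarray | None = None,
                   discount_rate: float | None = None) -> ScenarioOutcome:
        """Main lifetable: survival, person-years, morbidity, discounted
        HALYs and healthcare costs, given disease prevalence trajectories."""
        dw = self.dw if dw is None else dw
        cost_per_case = self.cost_per_case if cost_per_case is None else cost_per_case
        r = self.discount_rate if discount_rate is None else discount_rate

        m = self.residual_g + np.einsum("dsy,dsy->sy", p, self.cf_g)
        q = 1.0 - np.exp(-m)
        dead_frac = np.where(self.active, q, 1.0)  # absorb past age 100

        disc = (1.0 + r) ** (-np.arange(N_YEARS, dtype=float))
        dyld = np.einsum("dsy,d->sy", p - self.p_base, dw)
        yld = np.clip(self.yld_g + dyld
                      + (child_yld_delta if child_yld_delta is not None else 0.0),
                      0.0, 1.0)
        unit_cost = np.einsum("dsy,d->sy", p, cost_per_case)

        # survivorship l at the start of each year, then half-cycle L
        surv = np.cumprod(1.0 - dead_frac, axis=1)
        l = np.concatenate([np.ones((self.n_s, 1)), surv[:, :-1]], axis=1)
        L = np.where(self.active, 0.5 * (l + surv), 0.0)

        wL = self.count[:, None] * L
        haly_stream = disc * np.sum(wL * (1.0 - yld), axis=0)
        cost_stream = disc * np.sum(wL * unit_cost, axis=0)
        return ScenarioOutcome(
            label=label,
            total_halys=float(haly_stream.sum()),
            total_cost=float(cost_stream.sum()),
            haly_stream=haly_stream,
            cost_stream=cost_stream,
        )

    # ------------------------------------------------------------------
    def run_baseline(self, dw=None, cost_per_case=None,
                     discount_rate=None) -> ScenarioOutcome:
        if not hasattr(self, "_p_baseline"):
            self._p_baseline = self._disease_compartments(None)
        return self._aggregate(self._p_baseline, "baseline", None, dw,
                               cost_per_case, discount_rate)

    def run_scenario(self, pif_table: np.ndarray | None,
                     child_yld_delta: np.ndarray | None = None,
                     dw=None, cost_per_case=None,
                     discount_rate=None) -> ScenarioOutcome:
        """Run with incidence scaled by (1 - PIF); a null PIF table
        reproduces the baseline exactly."""
        if pif_table is None:
            return self.run_baseline(dw, cost_per_case, discount_rate)
        p = self._disease_compartments(1.0 - pif_table)
        return self._aggregate(p, "intervention", child_yld_delta, dw,
                               cost_per_case, discount_rate)

    def _child_yld_delta(self, deltas: RiskDeltas,
                         coeff: float | None = None) -> np.ndarray:
        """Quality decrement difference from the childhood-BMI term:
        coeff * [max(0, mean+shift-ref) - max(0, mean-ref)] for attained
        ages 2-17 (ref is infinite for adults, zeroing the term)."""
        coeff = self.child_hrql_coeff if coeff is None else coeff
        mb = self.mean_bmi_g
        ref = self.child_ref_g
        base_excess = np.maximum(0.0, mb - ref)
        scen_excess = np.maximum(0.0, mb + deltas.bmi_shift - ref)
        out = coeff * (scen_excess - base_excess)
        return np.where(np.isfinite(ref), out, 0.0)

    def evaluate(self, spec: InterventionSpec,
                 overrides: dict | None = None) -> EvaluationOutput:
        """Incremental HALYs and healthcare cost offsets versus baseline.

        ``overrides`` may carry sampled parameter values:
        ``effect_size``, ``uptake``, ``rr_bmi``/``rr_pa`` (dicts by
        disease), ``dw``/``cost_per_case`` (dicts by disease),
        ``discount_rate``, ``child_hrql_coeff``.
        """
        ov = overrides or {}
        if "effect_size" in ov or "uptake" in ov:
            spec = InterventionSpec(**{
                **{f: getattr(spec, f) for f in (
                    "name", "classification", "target_age_lo", "target_age_hi",
                    "target_sexes", "effect_type", "effect_se",
                    "implementation_years", "maintenance_type",
                    "maintenance_end_year", "cost_components")},
                "effect_size": ov.get("effect_size", spec.effect_size),
                "uptake": float(np.clip(ov.get("uptake", spec.uptake), 0.0, 1.0)),
            })
        deltas = build_risk_deltas(
            spec, self.population, self.bundle.growth_reference,
            self.energy_params, n_years=N_YEARS,
            pa_affects_bmi=self.pa_affects_bmi,
        )
        pif = pifs_for_intervention(
            deltas, self.bundle.diseases, self.pif_calc,
            rr_bmi_overrides=ov.get("rr_bmi"), rr_pa_overrides=ov.get("rr_pa"),
            pa_related=self._pa_related,
        )
        dw, cost = self._override_arrays(ov)
        r = ov.get("discount_rate")
        child = self._child_yld_delta(deltas, ov.get("child_hrql_coeff"))
        baseline = self.run_baseline(dw, cost, r)
        scenario = self.run_scenario(pif, child, dw, cost, r)
        return EvaluationOutput(
            halys_gained=scenario.total_halys - baseline.total_halys,
            cost_offsets=baseline.total_cost - scenario.total_cost,
            baseline=baseline,
            scenario=scenario,
            haly_stream=scenario.haly_stream - baseline.haly_stream,
            offset_stream=baseline.cost_stream - scenario.cost_stream,
        )

    def _override_arrays(self, ov: dict):
        dw = None
        cost = None
        if "dw" in ov:
            dw = self.dw.copy()
            for did, v in ov["dw"].items():
                dw[DISEASE_IDS.index(did)] = v
        if "cost_per_case" in ov:
            cost = self.cost_per_case.copy()
            for did, v in ov["cost_per_case"].items():
                cost[DISEASE_IDS.index(did)] = v
        return dw, cost


def run_lifetable(bundle: Bundle, pif_table: np.ndarray | None = None,
                  discount_rate: float = 0.03,
                  child_hrql_coeff: float = 0.005) -> ScenarioOutcome:
    """Convenience wrapper: one scenario run over a validated bundle."""
    ev = Evaluator(bundle, discount_rate=discount_rate,
                   child_hrql_coeff=child_hrql_coeff)
    return ev.run_scenario(pif_table)


def evaluate_intervention(bundle: Bundle, spec: InterventionSpec | str,
                          discount_rate: float = 0.03,
                          child_hrql_coeff: float = 0.005,
                          pa_affects_bmi: bool = True) -> EvaluationOutput:
    """Incremental HALYs gained and healthcare cost offsets for one
    intervention against the no-intervention comparator."""
    if isinstance(spec, str):
        spec = bundle.get_intervention(spec)
    ev = Evaluator(bundle, discount_rate=discount_rate,
                   child_hrql_coeff=child_hrql_coeff,
                   pa_affects_bmi=pa_affects_bmi)
    return ev.evaluate(spec)
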
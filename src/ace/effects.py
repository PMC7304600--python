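"""Translate intervention effect sizes into risk-factor changes.

Interventions express their effect as a change in energy intake (kJ/day),
physical activity (MET-minutes/week), BMI units, or BMI z-score units.
This module converts each of those, per population stratum, into a signed
BMI shift and (for activity effects) a shift of mass between ordered
physical-activity bands, scaled by uptake and by the maintenance-of-effect
profile over time.

Sign convention: beneficial effects never increase the BMI shift.  kJ/day
and BMI effects are negative when beneficial; MET-min/week effects are
positive when beneficial (extra expenditure), and the conversion chain
flips the sign when turning expenditure into an intake-equivalent deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import InterventionSpec


#: Oldest age treated as a child for energy-balance and growth-reference
#: purposes.
CHILD_AGE_MAX = 17


@dataclass(frozen=True)
class EnergyBalanceParams:
    """Steady-state energy-balance coefficients.

    ``rho_adult``/``rho_child`` give the sustained change in daily energy
    intake (kJ/day) associated with one kilogram of steady-state weight
    change; ``met_kcal_coeff`` is the energy cost of activity in kcal per
    kg body mass per MET-minute.
    """

    rho_adult: float = 94.0
    rho_child: float = 100.0
    met_kcal_coeff: float = 0.0175
    kj_per_kcal: float = 4.184

    def __post_init__(self):
        for name in ("rho_adult", "rho_child", "met_kcal_coeff", "kj_per_kcal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EnergyBalanceParams.{name}: must be > 0")

    @classmethod
    def from_config(cls, config: dict) -> "EnergyBalanceParams":
        eb = config.get("energy_balance", {})
        return cls(
            rho_adult=eb.get("rho_adult", 94.0),
            rho_child=eb.get("rho_child", 100.0),
            met_kcal_coeff=eb.get("met_kcal_coeff", 0.0175),
            kj_per_kcal=eb.get("kj_per_kcal", 4.184),
        )


@dataclass
class RiskFactorDelta:
    """Per-stratum risk-factor change for one model year."""

    year: int
    bmi_shift: np.ndarray  # kg/m^2, one entry per population stratum
    pa_transition: np.ndarray | None = None  # row-stochastic [4, 4], shared

    def __post_init__(self):
        if self.year < 0:
            raise ValueError("RiskFactorDelta.year: must be >= 0")
        if not np.all(np.isfinite(self.bmi_shift)):
            raise ValueError("RiskFactorDelta.bmi_shift: must be finite")
        if self.pa_transition is not None:
            if np.abs(self.pa_transition.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("RiskFactorDelta.pa_transition: rows must sum to 1")


def kj_to_weight(delta_kj_per_day: float, age_group: str,
                 params: EnergyBalanceParams) -> float:
    """Steady-state weight change (kg) for a sustained intake change.

    ``age_group`` is ``"adult"`` (18+) or ``"child"``.
    """
    if age_group not in ("adult", "child"):
        raise ValueError(f"age_group must be 'adult' or 'child', got {age_group!r}")
    rho = params.rho_adult if age_group == "adult" else params.rho_child
    return delta_kj_per_day / rho


def weight_to_bmi_delta(delta_kg: float, mean_height_m: float) -> float:
    """BMI change from a weight change at a given (fixed) height."""
    if mean_height_m <= 0:
        raise ValueError("mean_height_m must be > 0")
    return delta_kg / (mean_height_m ** 2)


def lms_bmi(z: float | np.ndarray, L: float, M: float, S: float):
    """BMI at z-score ``z`` under the LMS transform."""
    if L == 0:
        return M * np.exp(S * z)
    return M * np.power(1.0 + L * S * np.asarray(z), 1.0 / L)


def zscore_delta_to_bmi_delta(z0: float, delta_z: float, age: int, sex: str,
                              growth_ref: pd.DataFrame) -> float:
    """BMI change for a child moving from z-score ``z0`` to ``z0+delta_z``."""
    if not (2 <= age <= CHILD_AGE_MAX):
        raise ValueError(f"z-score conversion requires age in [2, {CHILD_AGE_MAX}], got {age}")
    for z in (z0, z0 + delta_z):
        if not -4 <= z <= 4:
            raise ValueError(f"z-score {z} outside supported range [-4, 4]")
    row = growth_ref[(growth_ref["age"] == age) & (growth_ref["sex"] == sex)]
    if row.empty:
        raise KeyError(f"growth reference has no entry for age={age}, sex={sex}")
    L, M, S = (float(row.iloc[0][c]) for c in ("L", "M", "S"))
    return float(lms_bmi(z0 + delta_z, L, M, S) - lms_bmi(z0, L, M, S))


def met_to_kj_per_day(delta_met_min_per_week: float, body_mass_kg: float,
                      params: EnergyBalanceParams) -> float:
    """Daily energy expenditure change (kJ/day) for a change in weekly
    MET-minutes.

    A positive MET increase yields positive extra expenditure; callers
    treating it as an intake-equivalent deficit must negate it (as
    :func:`build_risk_deltas` does).
    """
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    return (delta_met_min_per_week * body_mass_kg * params.met_kcal_coeff
            * params.kj_per_kcal / 7.0)


def effect_at_time(spec: InterventionSpec, year: int) -> float:
    """Maintenance-of-effect scale in [0, 1] at ``year`` years after start.

    * ``sustained``: 1 for every year (effects maintained for life).
    * ``step_to_zero(E)``: 1 before year E, 0 from year E on.
    * ``linear_decay(E)``: 1 throughout implementation, then linear to 0
      at year E.
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    kind = spec.maintenance_type
    if kind == "sustained":
        return 1.0
    end = spec.maintenance_end_year
    if kind == "step_to_zero":
        return 1.0 if year < end else 0.0
    # linear_decay
    impl = spec.implementation_years
    if year < impl:
        return 1.0
    if year >= end:
        return 0.0
    return (end - year) / (end - impl)


def _pa_upshift_matrix(moved_fraction: float) -> np.ndarray:
    """Transition matrix moving ``moved_fraction`` of each non-top activity
    band one band upward."""
    m = float(np.clip(moved_fraction, 0.0, 1.0))
    T = np.eye(4)
    for i in range(3):
        T[i, i] = 1.0 - m
        T[i, i + 1] = m
    return T


class RiskDeltas:
    """Risk-factor deltas for every stratum and model year.

    ``bmi_shift`` has shape [n_strata, n_years]; ``pa_moved`` gives the
    uptake-weighted fraction of each non-top activity band moved one band
    up, per year (zero when the intervention has no activity pathway).
    ``targeted`` marks the strata inside the intervention's age/sex target.
    """

    def __init__(self, bmi_shift: np.ndarray, pa_moved: np.ndarray,
                 targeted: np.ndarray):
        self.bmi_shift = bmi_shift
        self.pa_moved = pa_moved
        self.targeted = targeted

    @property
    def n_years(self) -> int:
        return self.bmi_shift.shape[1]

    def at(self, year: int) -> RiskFactorDelta:
        moved = float(self.pa_moved[year])
        return RiskFactorDelta(
            year=year,
            bmi_shift=self.bmi_shift[:, year],
            pa_transition=_pa_upshift_matrix(moved) if moved > 0 else None,
        )


def build_risk_deltas(spec: InterventionSpec, population: pd.DataFrame,
                      growth_ref: pd.DataFrame,
                      params: EnergyBalanceParams | None = None,
                      n_years: int = 99,
                      pa_affects_bmi: bool = True) -> RiskDeltas:
    """Compose the conversion chain for one intervention.

    The per-stratum base BMI shift is computed once from the stratum's
    baseline age (heights and growth-reference parameters frozen at entry),
    then scaled by uptake and the maintenance profile each year.  Strata
    outside the age/sex target receive zero deltas.  Activity effects also
    generate a BMI shift via the MET -> kJ deficit chain unless
    ``pa_affects_bmi`` is false.
    """
    params = params or EnergyBalanceParams()
    ages = population["age"].to_numpy()
    sexes = population["sex"].to_numpy()
    heights = population["mean_height"].to_numpy()
    mean_bmi = np.exp(population["bmi_mu"].to_numpy()
                      + 0.5 * population["bmi_sigma"].to_numpy() ** 2)

    targeted = (ages >= spec.target_age_lo) & (ages <= spec.target_age_hi)
    if spec.target_sexes != "both":
        targeted &= sexes == spec.target_sexes

    if spec.effect_type == "bmi_z_delta" and spec.target_age_hi > CHILD_AGE_MAX:
        raise ValueError(
            f"{spec.name!r}: bmi_z_delta effects apply to children only "
            f"(target ages must lie within [2, {CHILD_AGE_MAX}])"
        )

    base_shift = np.zeros(len(population))
    pa_effect = spec.effect_type == "met_min_per_week"

    for i in np.nonzero(targeted)[0]:
        age, sex = int(ages[i]), sexes[i]
        group = "child" if age <= CHILD_AGE_MAX else "adult"
        if spec.effect_type == "bmi_delta":
            base_shift[i] = spec.effect_size
        elif spec.effect_type == "bmi_z_delta":
            base_shift[i] = zscore_delta_to_bmi_delta(0.0, spec.effect_size,
                                                      age, sex, growth_ref)
        elif spec.effect_type == "kj_per_day":
            dkg = kj_to_weight(spec.effect_size, group, params)
            base_shift[i] = weight_to_bmi_delta(dkg, heights[i])
        elif spec.effect_type == "met_min_per_week":
            if pa_affects_bmi:
                body_mass = mean_bmi[i] * heights[i] ** 2
                dkj = met_to_kj_per_day(spec.effect_size, body_mass, params)
                # expenditure increase == uncompensated intake deficit
                dkg = kj_to_weight(-dkj, group, params)
                base_shift[i] = weight_to_bmi_delta(dkg, heights[i])

    scale = np.array([effect_at_time(spec, y) for y in range(n_years)])
    bmi_shift = np.outer(base_shift * spec.uptake, scale)
    pa_moved = (spec.uptake * scale) if pa_effect else np.zeros(n_years)
    return RiskDeltas(bmi_shift=bmi_shift, pa_moved=pa_moved, targeted=targeted)
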
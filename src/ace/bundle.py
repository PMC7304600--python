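"""Data bundle: containers, CSV round-trip and validation.

A bundle is the complete set of inputs the model needs: an age x sex
population with BMI and physical-activity exposure distributions, a disease
catalogue with age- and sex-specific rates, risk-factor relative risks, an
LMS growth reference for children, and intervention specifications with
their cost components.  On disk a bundle is a directory of UTF-8 CSV files.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered physical-activity categories (least to most active) and the
#: MET-minutes/week midpoint assigned to each band.
PA_CATEGORIES = ("inactive", "low", "moderate", "high")
PA_MIDPOINTS = (100.0, 400.0, 1000.0, 2000.0)

SEXES = ("female", "male")
AGE_MIN, AGE_MAX = 2, 100

DISEASE_IDS = (
    "kidney_cancer",
    "colorectal_cancer",
    "endometrial_cancer",
    "breast_cancer",
    "type2_diabetes",
    "hypertensive_heart_disease",
    "ischaemic_heart_disease",
    "stroke",
    "osteoarthritis",
)
#: Diseases causally related to physical activity (the remaining four are
#: related to BMI only; all nine are BMI-related).
PA_DISEASES = frozenset(
    {
        "colorectal_cancer",
        "breast_cancer",
        "type2_diabetes",
        "ischaemic_heart_disease",
        "stroke",
    }
)

EFFECT_TYPES = ("kj_per_day", "met_min_per_week", "bmi_delta", "bmi_z_delta")
MAINTENANCE_TYPES = ("sustained", "step_to_zero", "linear_decay")
SECTORS = ("federal_govt", "state_govt", "local_govt", "industry", "individual")
PUBLIC_SECTORS = frozenset({"federal_govt", "state_govt", "local_govt"})


class BundleValidationError(ValueError):
    """A bundle table violates a structural or numeric invariant."""


class BundleIOError(ValueError):
    """A bundle file is missing or malformed on disk."""


@dataclass(frozen=True)
class CostComponent:
    label: str
    sector: str
    amount: float  # AUD/year, or hours/year when time_cost is set
    year_first: int
    year_last: int
    health_related: bool = False
    time_cost: bool = False
    source_year: int = 2010


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention: targeting, effect, maintenance and costs.

    ``effect_size`` is signed: negative kJ/day or BMI(-z) effects and
    positive MET-min/week effects are beneficial.
    """

    name: str
    classification: str  # regulatory | program
    target_age_lo: int
    target_age_hi: int
    target_sexes: str  # both | female | male
    effect_type: str
    effect_size: float
    effect_se: float
    uptake: float
    implementation_years: int = 1
    maintenance_type: str = "sustained"
    maintenance_end_year: int | None = None
    cost_components: tuple[CostComponent, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.effect_type not in EFFECT_TYPES:
            raise BundleValidationError(
                f"interventions.effect_type: unknown effect type {self.effect_type!r}"
            )
        if not 0.0 <= self.uptake <= 1.0:
            raise BundleValidationError(
                f"interventions.uptake: {self.uptake} outside [0, 1] for {self.name!r}"
            )
        if self.implementation_years < 1:
            raise BundleValidationError(
                f"interventions.implementation_years: must be >= 1 for {self.name!r}"
            )
        if self.maintenance_type not in MAINTENANCE_TYPES:
            raise BundleValidationError(
                f"interventions.maintenance_type: unknown type {self.maintenance_type!r}"
            )
        if self.maintenance_type == "linear_decay":
            if self.maintenance_end_year is None or (
                self.maintenance_end_year < self.implementation_years
            ):
                raise BundleValidationError(
                    "interventions.maintenance_end_year: linear_decay end year must "
                    f"be >= implementation_years for {self.name!r}"
                )


@dataclass
class Bundle:
    """In-memory bundle; each table is a pandas DataFrame."""

    population: pd.DataFrame
    diseases: pd.DataFrame
    rr: pd.DataFrame
    growth_reference: pd.DataFrame
    interventions: pd.DataFrame
    cost_components: pd.DataFrame

    def intervention_names(self) -> list[str]:
        return list(self.interventions["name"])

    def get_intervention(self, name: str) -> InterventionSpec:
        rows = self.interventions[self.interventions["name"] == name]
        if rows.empty:
            raise KeyError(f"no intervention named {name!r} in bundle")
        row = rows.iloc[0]
        comps = []
        cc = self.cost_components[self.cost_components["intervention"] == name]
        for _, c in cc.iterrows():
            comps.append(
                CostComponent(
                    label=str(c["label"]),
                    sector=str(c["sector"]),
                    amount=float(c["amount"]),
                    year_first=int(c["year_first"]),
                    year_last=int(c["year_last"]),
                    health_related=bool(c["health_related"]),
                    time_cost=bool(c["time_cost"]),
                    source_year=int(c.get("source_year", 2010)),
                )
            )
        end = row["maintenance_end_year"]
        end = None if pd.isna(end) else int(end)
        return InterventionSpec(
            name=str(row["name"]),
            classification=str(row["classification"]),
            target_age_lo=int(row["target_age_lo"]),
            target_age_hi=int(row["target_age_hi"]),
            target_sexes=str(row["target_sexes"]),
            effect_type=str(row["effect_type"]),
            effect_size=float(row["effect_size"]),
            effect_se=float(row["effect_se"]),
            uptake=float(row["uptake"]),
            implementation_years=int(row["implementation_years"]),
            maintenance_type=str(row["maintenance_type"]),
            maintenance_end_year=end,
            cost_components=tuple(comps),
        )

    def copy(self) -> "Bundle":
        return Bundle(**{f.name: getattr(self, f.name).copy() for f in dataclasses.fields(self)})


_REQUIRED_COLUMNS = {
    "population.csv": [
        "age", "sex", "count", "bmi_mu", "bmi_sigma",
        "pa_inactive", "pa_low", "pa_moderate", "pa_high",
        "mean_height", "mortality_all_cause", "yld_all_cause",
    ],
    "diseases.csv": [
        "disease_id", "age", "sex", "incidence", "case_fatality", "remission",
        "disability_weight", "annual_cost_per_case", "bmi_related",
        "pa_related", "sex_restriction",
    ],
    "rr.csv": [
        "disease_id", "risk_factor", "form", "rr_per_unit",
        "rr_inactive", "rr_low", "rr_moderate", "rr_high", "log_se", "tmrel",
    ],
    "growth_reference.csv": ["age", "sex", "L", "M", "S"],
    "interventions.csv": [
        "name", "classification", "target_age_lo", "target_age_hi",
        "target_sexes", "effect_type", "effect_size", "effect_se", "uptake",
        "implementation_years", "maintenance_type", "maintenance_end_year",
    ],
    "cost_components.csv": [
        "intervention", "label", "sector", "amount", "year_first", "year_last",
        "health_related", "time_cost", "source_year",
    ],
}

_ATTR_FOR_FILE = {
    "population.csv": "population",
    "diseases.csv": "diseases",
    "rr.csv": "rr",
    "growth_reference.csv": "growth_reference",
    "interventions.csv": "interventions",
    "cost_components.csv": "cost_components",
}


def save_bundle(bundle: Bundle, path: str) -> None:
    """Write all bundle tables as CSV files under ``path``.

    Floats are written with shortest round-trip repr, so a save/load cycle
    is lossless at full double precision.
    """
    os.makedirs(path, exist_ok=True)
    for fname, attr in _ATTR_FOR_FILE.items():
        df = getattr(bundle, attr)
        df.to_csv(os.path.join(path, fname), index=False)


def load_bundle(path: str) -> Bundle:
    """Read a bundle directory; column lookup is header-keyed, so column
    order in the files is irrelevant.  Missing files or columns raise
    :class:`BundleIOError` naming the file and column."""
    tables = {}
    for fname, attr in _ATTR_FOR_FILE.items():
        fpath = os.path.join(path, fname)
        if not os.path.exists(fpath):
            raise BundleIOError(f"bundle file missing: {fname}")
        df = pd.read_csv(fpath)
        for col in _REQUIRED_COLUMNS[fname]:
            if col not in df.columns:
                raise BundleIOError(f"{fname}: missing required column {col!r}")
        if fname == "diseases.csv":
            # absent sex restriction is the empty string, not NaN
            df["sex_restriction"] = df["sex_restriction"].fillna("")
        # canonical column order independent of on-disk order
        tables[attr] = df[_REQUIRED_COLUMNS[fname]]
    return Bundle(**tables)


def validate_bundle(bundle: Bundle) -> None:
    """Check every type invariant; raise BundleValidationError naming the
    offending table and field."""
    pop = bundle.population
    if len(pop) != (AGE_MAX - AGE_MIN + 1 - 0) * 2 and len(pop) == 0:
        raise BundleValidationError("population: empty table")
    if (pop["bmi_sigma"] <= 0).any():
        raise BundleValidationError("population.bmi_sigma: must be > 0")
    if (pop["count"] < 0).any():
        raise BundleValidationError("population.count: must be >= 0")
    pa = pop[["pa_inactive", "pa_low", "pa_moderate", "pa_high"]].to_numpy()
    if np.abs(pa.sum(axis=1) - 1.0).max() > 1e-9:
        raise BundleValidationError("population.pa_*: prevalences must sum to 1")
    if (pa < 0).any():
        raise BundleValidationError("population.pa_*: prevalences must be >= 0")
    if (pop["mean_height"] <= 0).any():
        raise BundleValidationError("population.mean_height: must be > 0")
    if ((pop["yld_all_cause"] < 0) | (pop["yld_all_cause"] >= 1)).any():
        raise BundleValidationError("population.yld_all_cause: must lie in [0, 1)")
    if (~pop["sex"].isin(SEXES)).any():
        raise BundleValidationError("population.sex: must be female or male")
    if ((pop["age"] < AGE_MIN) | (pop["age"] > AGE_MAX)).any():
        raise BundleValidationError(f"population.age: must lie in [{AGE_MIN}, {AGE_MAX}]")

    dis = bundle.diseases
    ids = set(dis["disease_id"].unique())
    if len(ids) != 9:
        raise BundleValidationError("diseases.disease_id: expected exactly 9 diseases")
    for col in ("incidence", "case_fatality", "remission"):
        if (dis[col] < 0).any():
            raise BundleValidationError(f"diseases.{col}: rates must be >= 0")
    if ((dis["disability_weight"] < 0) | (dis["disability_weight"] > 1)).any():
        raise BundleValidationError("diseases.disability_weight: must lie in [0, 1]")
    meta = dis.groupby("disease_id").first()
    if int(meta["pa_related"].sum()) != 5:
        raise BundleValidationError("diseases.pa_related: exactly 5 diseases must be PA-related")
    if not meta["bmi_related"].all():
        raise BundleValidationError("diseases.bmi_related: all diseases must be BMI-related")

    rr = bundle.rr
    if ((rr["tmrel"] < 18) | (rr["tmrel"] > 25)).any():
        raise BundleValidationError("rr.tmrel: must lie in [18, 25]")
    bmi_rows = rr[rr["risk_factor"] == "bmi"]
    if (bmi_rows["rr_per_unit"] <= 0).any():
        raise BundleValidationError("rr.rr_per_unit: must be > 0")
    pa_rows = rr[rr["risk_factor"] == "pa"]
    cat = pa_rows[["rr_inactive", "rr_low", "rr_moderate", "rr_high"]].to_numpy()
    if len(cat) and (cat <= 0).any():
        raise BundleValidationError("rr.rr_<category>: must be > 0")

    gr = bundle.growth_reference
    if (gr["M"] <= 0).any():
        raise BundleValidationError("growth_reference.M: must be > 0")
    if (gr["S"] <= 0).any():
        raise BundleValidationError("growth_reference.S: must be > 0")

    # mortality envelope: all-cause mortality must cover the disease-specific
    # mortality implied by steady-state prevalence at every age
    implied = _implied_disease_mortality(bundle)
    merged = pop.merge(implied, on=["age", "sex"], how="left")
    short = merged["mortality_all_cause"] + 1e-12 < merged["implied_mortality"].fillna(0.0)
    if short.any():
        raise BundleValidationError(
            "population.mortality_all_cause: below disease-implied mortality "
            f"for {int(short.sum())} strata"
        )

    # interventions validated row by row through the dataclass constructor
    for name in bundle.intervention_names():
        spec = bundle.get_intervention(name)
        for comp in spec.cost_components:
            if comp.amount < 0:
                raise BundleValidationError(
                    f"cost_components.amount: negative for {name!r}/{comp.label!r}"
                )
            if comp.year_last < comp.year_first:
                raise BundleValidationError(
                    f"cost_components.years: ill-ordered for {name!r}/{comp.label!r}"
                )
            if comp.sector not in SECTORS:
                raise BundleValidationError(
                    f"cost_components.sector: unknown sector {comp.sector!r}"
                )


def steady_state_prevalence(incidence: np.ndarray, case_fatality: np.ndarray,
                            remission: np.ndarray) -> np.ndarray:
    """Prevalence proportion by age implied by running the annual disease
    process from the youngest modelled age with S=1, C=0.

    Background mortality, being removed proportionally from the susceptible
    and diseased compartments, cancels in the prevalence proportion
    C/(S+C) and is therefore omitted here.  Rates are converted to annual
    probabilities via q = 1 - exp(-rate).

    Arrays are indexed by age offset (age - AGE_MIN); returns prevalence at
    the *start* of each age year.
    """
    n = len(incidence)
    S = np.empty(n + 1)
    C = np.empty(n + 1)
    S[0], C[0] = 1.0, 0.0
    qi = 1.0 - np.exp(-incidence)
    qf = 1.0 - np.exp(-case_fatality)
    qr = 1.0 - np.exp(-remission)
    for a in range(n):
        new = S[a] * qi[a]
        deaths = C[a] * qf[a]
        rem = C[a] * qr[a]
        S[a + 1] = S[a] - new + rem
        C[a + 1] = C[a] + new - deaths - rem
    tot = S + C
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, C / tot, 0.0)
    return p[:n]


def _implied_disease_mortality(bundle: Bundle) -> pd.DataFrame:
    """Sum over diseases of steady-state prevalence x case fatality, per
    age and sex."""
    out = []
    for (did, sex), grp in bundle.diseases.groupby(["disease_id", "sex"]):
        grp = grp.sort_values("age")
        p = steady_state_prevalence(
            grp["incidence"].to_numpy(),
            grp["case_fatality"].to_numpy(),
            grp["remission"].to_numpy(),
        )
        out.append(pd.DataFrame({
            "age": grp["age"].to_numpy(),
            "sex": sex,
            "implied": p * grp["case_fatality"].to_numpy(),
        }))
    df = pd.concat(out, ignore_index=True)
    return (
        df.groupby(["age", "sex"], as_index=False)["implied"]
        .sum()
        .rename(columns={"implied": "implied_mortality"})
    )
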
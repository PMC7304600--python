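import numpy as np
import pytest

import ace
from ace.lifetable import Evaluator


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 1), validated once per session."""
    b = ace.generate_bundle(seed=1)
    ace.validate_bundle(b)
    return b


@pytest.fixture(scope="session")
def evaluator(bundle):
    return Evaluator(bundle)


@pytest.fixture(scope="session")
def league_results():
    from ace.fixtures import results_from_league_fixture
    return results_from_league_fixture()


@pytest.fixture(scope="session")
def consideration_profiles():
    from ace.fixtures import profiles_from_considerations_fixture
    return profiles_from_considerations_fixture()


@pytest.fixture(scope="session")
def toy_bundle():
    """Two-active-disease bundle with a single unit cohort (age 60,
    female) and a simple sustained BMI intervention, for oracle
    comparisons against an individual-level microsimulation."""
    b = ace.generate_bundle(seed=7)
    pop = b.population.copy()
    pop["count"] = 0.0
    sel = (pop["age"] == 60) & (pop["sex"] == "female")
    pop.loc[sel, "count"] = 1.0
    b.population = pop

    dis = b.diseases.copy()
    keep = {"ischaemic_heart_disease": (30, 0.012, 0.02),
            "type2_diabetes": (20, 0.008, 0.005)}
    for did, grp in dis.groupby("disease_id"):
        if did in keep:
            onset, inc, cf = keep[did]
            m = dis["disease_id"] == did
            dis.loc[m, "incidence"] = np.where(dis.loc[m, "age"] >= onset, inc, 0.0)
            dis.loc[m, "case_fatality"] = cf
        else:
            m = dis["disease_id"] == did
            dis.loc[m, "incidence"] = 0.0
            dis.loc[m, "case_fatality"] = 0.0
    b.diseases = dis

    # rebuild the mortality envelope for the altered disease rates:
    # flat background plus the disease-implied part
    from ace.synthetic import _implied_mortality_frame
    implied = _implied_mortality_frame(dis)
    pop = b.population.merge(implied, on=["age", "sex"], how="left")
    pop["mortality_all_cause"] = 0.002 + pop["implied_mortality"].fillna(0.0)
    b.population = pop.drop(columns=["implied_mortality"])

    import pandas as pd
    toy_spec = pd.DataFrame([{
        "name": "toy_bmi_shift", "classification": "program",
        "target_age_lo": 55, "target_age_hi": 65, "target_sexes": "both",
        "effect_type": "bmi_delta", "effect_size": -1.0, "effect_se": 0.2,
        "uptake": 1.0, "implementation_years": 1,
        "maintenance_type": "sustained", "maintenance_end_year": np.nan,
    }])
    b.interventions = toy_spec
    b.cost_components = b.cost_components.iloc[0:0]
    ace.validate_bundle(b)
    return b
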
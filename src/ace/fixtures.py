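"""Packaged league-table fixtures.

Two small CSV files transcribe published point estimates for a 16-policy
obesity-prevention portfolio: a cost-effectiveness league table
(intervention costs, healthcare cost offsets, HALYs gained, ICERs) and the
matching implementation-considerations ratings.  They drive the
economics-only replay mode, which exercises ranking, dominance and summary
arithmetic without running the life table engine.

Sign convention on disk follows the printed table: the ``offsets`` column
is negative for savings; the loader flips it into the package convention
(``cost_offsets`` positive = savings).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .considerations import ConsiderationProfile, profiles_from_frame
from .economics import EvaluationResult, compute_icer, DEFAULT_WTP


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("ace.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        # keep "n/a" ratings as literal strings; empty cells stay NaN
        return pd.read_csv(path, keep_default_na=False,
                           na_values=[""])


def load_league_fixture() -> pd.DataFrame:
    """Cost-effectiveness league-table fixture (16 rows)."""
    return _read("table3_fixture.csv")


def load_considerations_fixture() -> pd.DataFrame:
    """Implementation-considerations fixture (16 rows)."""
    return _read("table4_fixture.csv")


def results_from_league_fixture(df: pd.DataFrame | None = None,
                                wtp: float = DEFAULT_WTP
                                ) -> list[EvaluationResult]:
    """Rebuild EvaluationResult rows from printed point estimates.

    Net cost is taken from the printed column (printed totals are rounded,
    so recomputing it from cost minus offsets can differ slightly); the
    dominance class is re-derived from the printed net cost and HALYs.
    """
    if df is None:
        df = load_league_fixture()
    out = []
    for _, row in df.iterrows():
        net = float(row["net_cost"])
        halys = float(row["halys"])
        icer, klass = compute_icer(net, halys, wtp)
        if not pd.isna(row["icer"]):
            # printed ICERs were computed from unrounded costs; prefer them
            # over a ratio of rounded table entries
            icer = float(row["icer"])
        out.append(EvaluationResult(
            name=str(row["intervention"]),
            classification=str(row["classification"]),
            halys_gained=halys,
            intervention_cost_total=float(row["total_cost"]),
            intervention_cost_first3y=float(row["first3y_cost"]),
            cost_offsets=-float(row["offsets"]),
            net_cost=net,
            icer=icer,
            dominance_class=klass,
        ))
    return out


def profiles_from_considerations_fixture(df: pd.DataFrame | None = None
                                         ) -> list[ConsiderationProfile]:
    if df is None:
        df = load_considerations_fixture()
    df = df.rename(columns={"intervention": "name"})
    return profiles_from_frame(df)
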
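"""End-to-end study orchestration.

Two execution modes:

* ``full`` — generate or load a data bundle, run the multi-state life
  table for every intervention against the no-intervention comparator,
  cost the interventions, and assemble the league table and portfolio
  summary (optionally with Monte Carlo uncertainty intervals);
* ``tables-only`` — replay printed league-table and considerations
  fixtures through the economics and ranking machinery without invoking
  the life table engine.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import fixtures
from .bundle import Bundle, load_bundle, validate_bundle
from .considerations import rank_considerations
from .economics import (
    CostingRules,
    DEFAULT_WTP,
    EvaluationResult,
    cost_intervention,
    league_table_frame,
    make_result,
    portfolio_summary,
)
from .lifetable import Evaluator
from .synthetic import generate_bundle, make_config
from .uncertainty import run_monte_carlo

log = logging.getLogger("ace")


@dataclass
class StudyConfig:
    bundle_path: str | None = None  # None: generate a synthetic bundle
    mode: str = "full"              # full | tables-only
    discount_rate: float = 0.03
    wtp: float = DEFAULT_WTP
    n_iterations: int = 2000        # 1 = deterministic only
    seed: int = 0
    output_dir: str = "ace_output"
    pa_affects_bmi: bool = True
    child_hrql_coeff: float = 0.005
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("StudyConfig.discount_rate: must be >= 0")
        if self.wtp <= 0:
            raise ValueError("StudyConfig.wtp: must be > 0")
        if self.n_iterations < 1:
            raise ValueError("StudyConfig.n_iterations: must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown study config keys: {sorted(unknown)}")
        return cls(**raw)


def evaluate_bundle(bundle: Bundle, config: StudyConfig,
                    monte_carlo: bool = False) -> list[EvaluationResult]:
    """Deterministic evaluation of every intervention in the bundle,
    optionally followed by Monte Carlo uncertainty."""
    validate_bundle(bundle)
    ev = Evaluator(bundle, discount_rate=config.discount_rate,
                   child_hrql_coeff=config.child_hrql_coeff,
                   pa_affects_bmi=config.pa_affects_bmi)
    rules = CostingRules()
    results = []
    for name in bundle.intervention_names():
        t0 = time.perf_counter()
        try:
            spec = bundle.get_intervention(name)
            out = ev.evaluate(spec)
            cost = cost_intervention(spec, rules, config.discount_rate)
            res = make_result(name, spec.classification, out.halys_gained,
                              cost, out.cost_offsets, wtp=config.wtp)
            if monte_carlo and config.n_iterations > 1:
                mc = run_monte_carlo(bundle, spec, n=config.n_iterations,
                                     seed=config.seed,
                                     discount_rate=config.discount_rate,
                                     wtp=config.wtp, rules=rules, evaluator=ev)
                res.uncertainty = mc.outputs
            results.append(res)
            log.info("evaluated %s in %.2fs", name, time.perf_counter() - t0)
        except Exception as exc:
            raise RuntimeError(
                f"evaluation stage failed for intervention {name!r}: {exc}"
            ) from exc
    return results


def run_study(config: StudyConfig, monte_carlo: bool | None = None) -> dict:
    """Run a complete study and write artefacts to ``config.output_dir``.

    Returns a dict with the league table (DataFrame), portfolio summary,
    results list and, in tables-only mode, the considerations ranking.
    Outputs are deterministic for a fixed seed (byte-identical CSV files).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log.info("study mode=%s seed=%d", config.mode, config.seed)

    if config.mode == "tables-only":
        results = fixtures.results_from_league_fixture(wtp=config.wtp)
        profiles = fixtures.profiles_from_considerations_fixture()
        ranked_profiles = rank_considerations(profiles)
        considerations_df = pd.DataFrame([{
            "rank": i + 1, "intervention": p.name,
            "evidence_bmi": p.evidence_bmi,
            "evidence_pa_diet": p.evidence_pa_diet, "equity": p.equity,
            "favourable_ratings": p.favourable_count(),
        } for i, p in enumerate(ranked_profiles)])
    elif config.mode == "full":
        if config.bundle_path:
            bundle = load_bundle(config.bundle_path)
        else:
            bundle = generate_bundle(make_config(config.generator_overrides),
                                     seed=config.seed)
        if monte_carlo is None:
            monte_carlo = config.n_iterations > 1
        results = evaluate_bundle(bundle, config, monte_carlo=monte_carlo)
        considerations_df = None
    else:
        raise ValueError(f"unknown study mode {config.mode!r}")

    league = league_table_frame(results)
    summary = portfolio_summary(results, wtp=config.wtp)

    league.to_csv(os.path.join(config.output_dir, "league_table.csv"),
                  index=False)
    with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    if considerations_df is not None:
        considerations_df.to_csv(
            os.path.join(config.output_dir, "considerations.csv"), index=False)

    out = {"league_table": league, "summary": summary, "results": results}
    if considerations_df is not None:
        out["considerations"] = considerations_df
    return out
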
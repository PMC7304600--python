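"""Intervention costing, ICERs, dominance, league tables and portfolio
summaries.

Costing follows a limited societal perspective: components accrue to
government sectors, industry or individuals; time components are valued at
a gender-free wage rate plus salary on-costs (13% public / 14% private
sector) and 17.5% leave loading; monetary components are indexed to
2010 values with a health price index for health-related costs and a GDP
index otherwise, then discounted.

The incremental cost-effectiveness ratio (ICER) is net cost (intervention
cost minus healthcare cost offsets) per HALY gained against a
no-intervention comparator, judged against a willingness-to-pay threshold
of AUD 50,000 per HALY.  Interventions that gain health and save money are
*dominant* and carry no interpretable ICER; the league table ranks the
dominant block by total HALYs gained (descending) ahead of the remaining
interventions ranked by ICER (ascending), ties broken by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import InterventionSpec, PUBLIC_SECTORS

DEFAULT_WTP = 50_000.0

DOMINANT = "dominant"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"
DOMINATED = "dominated"
COST_SAVING_HEALTH_NEUTRAL = "cost_saving_health_neutral"


@dataclass
class CostingRules:
    """Wage loadings and price indices for the 2010 reference year."""

    oncost_public: float = 0.13
    oncost_private: float = 0.14
    leave_loading: float = 0.175
    wage_rate: float = 40.0  # AUD/hour, gender-free
    health_price_index: dict[int, float] = field(default_factory=lambda: {2010: 1.0})
    gdp_index: dict[int, float] = field(default_factory=lambda: {2010: 1.0})

    def index_to_2010(self, amount: float, source_year: int,
                      health_related: bool) -> float:
        idx = self.health_price_index if health_related else self.gdp_index
        name = "health_price_index" if health_related else "gdp_index"
        if source_year not in idx or 2010 not in idx:
            raise KeyError(f"{name}: no entry for year {source_year} (and 2010)")
        return amount * idx[2010] / idx[source_year]

    def value_time(self, hours: float, sector: str) -> float:
        oncost = (self.oncost_public if sector in PUBLIC_SECTORS
                  else self.oncost_private)
        return hours * self.wage_rate * (1.0 + oncost) * (1.0 + self.leave_loading)


@dataclass
class InterventionCost:
    yearly: np.ndarray            # undiscounted AUD by year since start
    total_discounted: float
    first3y_undiscounted: float


def cost_intervention(spec: InterventionSpec,
                      rules: CostingRules | None = None,
                      discount_rate: float = 0.03,
                      horizon: int = 99,
                      cost_scale: float = 1.0) -> InterventionCost:
    """Yearly, total discounted, and first-three-year intervention costs.

    The first-three-year figure is undiscounted (short-term budget impact).
    ``cost_scale`` multiplies every component (used by uncertainty and
    threshold analyses).
    """
    rules = rules or CostingRules()
    yearly = np.zeros(horizon)
    for comp in spec.cost_components:
        amount = comp.amount
        if comp.time_cost:
            amount = rules.value_time(amount, comp.sector)
        amount = rules.index_to_2010(amount, comp.source_year, comp.health_related)
        y0 = max(0, comp.year_first)
        y1 = min(horizon - 1, comp.year_last)
        if y1 >= y0:
            yearly[y0:y1 + 1] += amount
    yearly = yearly * cost_scale
    disc = (1.0 + discount_rate) ** (-np.arange(horizon, dtype=float))
    return InterventionCost(
        yearly=yearly,
        total_discounted=float(yearly @ disc),
        first3y_undiscounted=float(yearly[:3].sum()),
    )


@dataclass
class EvaluationResult:
    """League-table row for one intervention."""

    name: str
    classification: str
    halys_gained: float
    intervention_cost_total: float
    intervention_cost_first3y: float
    cost_offsets: float  # positive = healthcare savings
    net_cost: float
    icer: float | None
    dominance_class: str
    uncertainty: dict = field(default_factory=dict)
    considerations: dict = field(default_factory=dict)


def compute_icer(net_cost: float, halys_gained: float,
                 wtp: float = DEFAULT_WTP) -> tuple[float | None, str]:
    """ICER and dominance class from net cost and HALYs gained.

    Sign partition: health gain + net saving is dominant (no ICER); health
    gain + net cost yields an ICER classed against the threshold; health
    loss + net cost is dominated; health loss + net saving reports saving
    per HALY lost, flagged not cost-effective for review.  Zero health
    change: net cost > 0 is not cost-effective (infinite ICER); otherwise
    cost-saving-health-neutral.
    """
    if halys_gained > 0:
        if net_cost < 0:
            return None, DOMINANT
        icer = net_cost / halys_gained
        return icer, (COST_EFFECTIVE if icer < wtp else NOT_COST_EFFECTIVE)
    if halys_gained < 0:
        if net_cost > 0:
            return None, DOMINATED
        if net_cost < 0:
            return net_cost / halys_gained, NOT_COST_EFFECTIVE
        return None, DOMINATED
    # exactly zero health change
    if net_cost > 0:
        return float("inf"), NOT_COST_EFFECTIVE
    return None, COST_SAVING_HEALTH_NEUTRAL


def make_result(name: str, classification: str, halys_gained: float,
                cost: InterventionCost | float, cost_offsets: float,
                first3y: float | None = None,
                wtp: float = DEFAULT_WTP, **extra) -> EvaluationResult:
    """Assemble an EvaluationResult, deriving net cost, ICER and class."""
    if isinstance(cost, InterventionCost):
        total = cost.total_discounted
        first3y = cost.first3y_undiscounted
    else:
        total = float(cost)
        first3y = float(first3y if first3y is not None else cost)
    net = total - cost_offsets
    icer, klass = compute_icer(net, halys_gained, wtp)
    return EvaluationResult(
        name=name, classification=classification, halys_gained=halys_gained,
        intervention_cost_total=total, intervention_cost_first3y=first3y,
        cost_offsets=cost_offsets, net_cost=net, icer=icer,
        dominance_class=klass, **extra,
    )


def build_league_table(results: list[EvaluationResult]) -> list[EvaluationResult]:
    """Rank results: dominant block first by HALYs gained descending, then
    the rest by ICER ascending; residual ties alphabetical by name."""
    if not results:
        raise ValueError("league table requires at least one result")
    dominant = [r for r in results if r.dominance_class == DOMINANT]
    rest = [r for r in results if r.dominance_class != DOMINANT]
    dominant.sort(key=lambda r: (-r.halys_gained, r.name))
    rest.sort(key=lambda r: (r.icer if r.icer is not None else float("inf"), r.name))
    return dominant + rest


def league_table_frame(results: list[EvaluationResult]) -> pd.DataFrame:
    ranked = build_league_table(results)
    return pd.DataFrame([{
        "rank": i + 1, "intervention": r.name,
        "classification": r.classification,
        "dominance_class": r.dominance_class,
        "icer": r.icer, "halys_gained": r.halys_gained,
        "intervention_cost_total": r.intervention_cost_total,
        "intervention_cost_first3y": r.intervention_cost_first3y,
        "cost_offsets": r.cost_offsets, "net_cost": r.net_cost,
    } for i, r in enumerate(ranked)])


def mid50_range(values) -> tuple[float, float]:
    """Range of the middle 50% of values by rank-dropping: sort, drop
    floor(n/4) from each end, report (min, max) of the remainder."""
    v = np.sort(np.asarray(values, dtype=float))
    k = len(v) // 4
    kept = v[k:len(v) - k] if k > 0 else v
    return float(kept[0]), float(kept[-1])


def portfolio_summary(results: list[EvaluationResult],
                      wtp: float = DEFAULT_WTP) -> dict:
    """Cross-intervention arithmetic: counts by dominance class, short-term
    budget, class/classification means and their ratios, and middle-50%
    ranges of HALYs, intervention costs and net costs."""
    if not results:
        raise ValueError("portfolio summary requires at least one result")
    dom = [r for r in results if r.dominance_class == DOMINANT]
    nondom = [r for r in results if r.dominance_class != DOMINANT]
    ce = [r for r in results
          if r.dominance_class in (DOMINANT, COST_EFFECTIVE,
                                   COST_SAVING_HEALTH_NEUTRAL)]
    reg = [r for r in results if r.classification == "regulatory"]
    prog = [r for r in results if r.classification == "program"]

    def mean(rows, attr):
        return float(np.mean([getattr(r, attr) for r in rows])) if rows else float("nan")

    summary = {
        "n": len(results),
        "n_dominant": len(dom),
        "n_cost_effective": len(ce),
        "n_regulatory": len(reg),
        "n_program": len(prog),
        "first3y_budget": float(sum(r.intervention_cost_first3y for r in results)),
        "mean_cost_dominant": mean(dom, "intervention_cost_total"),
        "mean_cost_nondominant": mean(nondom, "intervention_cost_total"),
        "mean_halys_dominant": mean(dom, "halys_gained"),
        "mean_halys_nondominant": mean(nondom, "halys_gained"),
        "mean_cost_regulatory": mean(reg, "intervention_cost_total"),
        "mean_cost_program": mean(prog, "intervention_cost_total"),
        "mean_halys_regulatory": mean(reg, "halys_gained"),
        "mean_halys_program": mean(prog, "halys_gained"),
        "halys_mid50": mid50_range([r.halys_gained for r in results]),
        "cost_mid50": mid50_range([r.intervention_cost_total for r in results]),
        "net_cost_mid50": mid50_range([r.net_cost for r in results]),
        "icer_range_nondominant": (
            (min(r.icer for r in nondom if r.icer is not None),
             max(r.icer for r in nondom if r.icer is not None))
            if any(r.icer is not None for r in nondom) else (None, None)),
    }
    if dom and nondom:
        summary["cost_ratio_nondominant_over_dominant"] = (
            summary["mean_cost_nondominant"] / summary["mean_cost_dominant"])
        summary["halys_ratio_dominant_over_nondominant"] = (
            summary["mean_halys_dominant"] / summary["mean_halys_nondominant"])
    if reg and prog:
        summary["cost_ratio_program_over_regulatory"] = (
            summary["mean_cost_program"] / summary["mean_cost_regulatory"])
    return summary
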
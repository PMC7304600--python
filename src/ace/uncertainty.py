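"""Parameter uncertainty: Monte Carlo propagation, univariate sensitivity
and threshold analyses.

Monte Carlo draws every registered parameter distribution once per
iteration and runs baseline and intervention scenarios with the *same*
draw (common random numbers), so incremental outputs difference out shared
parameters.  Uncertainty intervals are percentile-based (95% by default).
Distribution families follow standard health-economics practice: lognormal
for relative risks, gamma for costs, beta for proportions, truncated
normal for effect sizes, degenerate for fixed values.

Parameter paths address the model:

* ``rr.<disease>.bmi``                — per-unit BMI relative risk
* ``rr.<disease>.pa``                 — multiplier on non-reference PA RRs
* ``intervention.effect_size``        — intervention effect size
* ``intervention.uptake``             — uptake proportion
* ``disease.<id>.annual_cost_per_case``
* ``disease.<id>.disability_weight``
* ``cost.scale``                      — multiplier on every cost component
* ``model.discount_rate``, ``model.child_hrql_coeff`` (sensitivity only)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import Bundle, InterventionSpec
from .economics import (
    CostingRules,
    DEFAULT_WTP,
    DOMINANT,
    compute_icer,
    cost_intervention,
)
from .lifetable import Evaluator

FAMILIES = ("lognormal", "gamma", "beta", "normal_truncated", "degenerate")


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: a model path, a family and hyperparameters."""

    path: str
    family: str
    params: dict

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        need = {
            "lognormal": {"mean", "log_se"},
            "gamma": {"mean", "se"},
            "beta": {"mean", "se"},
            "normal_truncated": {"mean", "se", "lo", "hi"},
            "degenerate": {"value"},
        }[self.family]
        missing = need - set(self.params)
        if missing:
            raise ValueError(
                f"{self.path}: family {self.family!r} missing hyperparameters "
                f"{sorted(missing)}"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "degenerate":
            return np.full(n, float(p["value"]))
        if self.family == "lognormal":
            # median-preserving draws around the point estimate
            return p["mean"] * np.exp(rng.normal(0.0, p["log_se"], size=n))
        if self.family == "gamma":
            mean, se = float(p["mean"]), float(p["se"])
            if se == 0:
                return np.full(n, mean)
            shape = (mean / se) ** 2
            scale = se**2 / mean
            return rng.gamma(shape, scale, size=n)
        if self.family == "beta":
            mean, se = float(p["mean"]), float(p["se"])
            if se == 0:
                return np.full(n, mean)
            nu = mean * (1 - mean) / se**2 - 1.0
            if nu <= 0:
                raise ValueError(f"{self.path}: beta se too large for mean {mean}")
            return rng.beta(mean * nu, (1 - mean) * nu, size=n)
        # truncated normal
        mean, se = float(p["mean"]), float(p["se"])
        if se == 0:
            return np.full(n, mean)
        a = (p["lo"] - mean) / se
        b = (p["hi"] - mean) / se
        return stats.truncnorm.rvs(a, b, loc=mean, scale=se, size=n,
                                   random_state=rng)


@dataclass
class MCResult:
    """Point estimates, draw means and percentile uncertainty intervals."""

    outputs: dict  # name -> {point, mean, lo, hi}
    n_iterations: int
    seed: int
    draws: pd.DataFrame = field(repr=False, default=None)


def default_distributions(bundle: Bundle, spec: InterventionSpec,
                          ) -> list[ParameterDistribution]:
    """Standard distribution set: lognormal RRs, truncated-normal effect
    size, beta uptake, gamma cost scale and disease costs."""
    dists: list[ParameterDistribution] = []
    rr = bundle.rr
    for _, row in rr[rr["risk_factor"] == "bmi"].iterrows():
        dists.append(ParameterDistribution(
            path=f"rr.{row['disease_id']}.bmi", family="lognormal",
            params={"mean": float(row["rr_per_unit"]),
                    "log_se": float(row["log_se"])},
        ))
    if spec.effect_type == "met_min_per_week":
        for _, row in rr[rr["risk_factor"] == "pa"].iterrows():
            dists.append(ParameterDistribution(
                path=f"rr.{row['disease_id']}.pa", family="lognormal",
                params={"mean": 1.0, "log_se": float(row["log_se"])},
            ))
    se = spec.effect_se
    dists.append(ParameterDistribution(
        path="intervention.effect_size", family="normal_truncated",
        params={"mean": spec.effect_size, "se": se,
                "lo": spec.effect_size - 4 * se, "hi": spec.effect_size + 4 * se},
    ))
    if 0 < spec.uptake < 1:
        dists.append(ParameterDistribution(
            path="intervention.uptake", family="beta",
            params={"mean": spec.uptake,
                    "se": min(0.1 * spec.uptake, 0.3 * spec.uptake * (1 - spec.uptake))},
        ))
    dists.append(ParameterDistribution(
        path="cost.scale", family="gamma", params={"mean": 1.0, "se": 0.1}))
    meta = bundle.diseases.groupby("disease_id").first()
    for did, row in meta.iterrows():
        dists.append(ParameterDistribution(
            path=f"disease.{did}.annual_cost_per_case", family="gamma",
            params={"mean": float(row["annual_cost_per_case"]),
                    "se": 0.2 * float(row["annual_cost_per_case"])},
        ))
    return dists


def _pa_reference(bundle: Bundle) -> dict:
    out = {}
    for _, row in bundle.rr[bundle.rr["risk_factor"] == "pa"].iterrows():
        out[row["disease_id"]] = np.array([
            row["rr_inactive"], row["rr_low"], row["rr_moderate"], row["rr_high"]])
    return out


def _overrides_from_draw(bundle: Bundle, values: dict,
                         pa_ref: dict | None = None) -> tuple[dict, float]:
    """Translate sampled path values into Evaluator overrides plus the
    cost-component scale factor."""
    ov: dict = {}
    cost_scale = 1.0
    if pa_ref is None:
        pa_ref = _pa_reference(bundle)
    for path, v in values.items():
        parts = path.split(".")
        if parts[0] == "rr" and parts[2] == "bmi":
            ov.setdefault("rr_bmi", {})[parts[1]] = v
        elif parts[0] == "rr" and parts[2] == "pa":
            vec = pa_ref[parts[1]].copy()
            vec[:3] = vec[:3] * v  # reference (most-active) band stays at 1
            ov.setdefault("rr_pa", {})[parts[1]] = vec
        elif path == "intervention.effect_size":
            ov["effect_size"] = v
        elif path == "intervention.uptake":
            ov["uptake"] = v
        elif parts[0] == "disease" and parts[2] == "annual_cost_per_case":
            ov.setdefault("cost_per_case", {})[parts[1]] = v
        elif parts[0] == "disease" and parts[2] == "disability_weight":
            ov.setdefault("dw", {})[parts[1]] = v
        elif path == "cost.scale":
            cost_scale = v
        elif path == "model.discount_rate":
            ov["discount_rate"] = v
        elif path == "model.child_hrql_coeff":
            ov["child_hrql_coeff"] = v
        else:
            raise KeyError(f"unknown parameter path {path!r}")
    return ov, cost_scale


def run_monte_carlo(bundle: Bundle, spec: InterventionSpec | str,
                    dists: list[ParameterDistribution] | None = None,
                    n: int = 2000, seed: int = 0,
                    discount_rate: float = 0.03, wtp: float = DEFAULT_WTP,
                    rules: CostingRules | None = None,
                    evaluator: Evaluator | None = None) -> MCResult:
    """Monte Carlo uncertainty for one intervention.

    Fully reproducible for a fixed seed: one child seed stream per
    distribution, all draws made up front.  Each iteration applies the same
    draw to baseline and scenario, so healthcare cost offsets stay
    internally consistent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(spec, str):
        spec = bundle.get_intervention(spec)
    dists = dists if dists is not None else default_distributions(bundle, spec)
    for d in dists:
        if d.family not in FAMILIES:  # re-validated before any model run
            raise ValueError(f"unknown family {d.family!r}")
    ev = evaluator or Evaluator(bundle, discount_rate=discount_rate)
    rules = rules or CostingRules()

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(dists))
    draw_mat = {
        d.path: d.sample(np.random.default_rng(s), n)
        for d, s in zip(dists, streams)
    }

    # deterministic point estimate
    det = ev.evaluate(spec)
    det_cost = cost_intervention(spec, rules, discount_rate)
    det_net = det_cost.total_discounted - det.cost_offsets
    det_icer, _ = compute_icer(det_net, det.halys_gained, wtp)

    halys = np.empty(n)
    offsets = np.empty(n)
    net = np.empty(n)
    icer = np.full(n, np.nan)
    pa_ref = _pa_reference(bundle)
    for i in range(n):
        values = {path: draw_mat[path][i] for path in draw_mat}
        ov, cost_scale = _overrides_from_draw(bundle, values, pa_ref)
        out = ev.evaluate(spec, overrides=ov)
        c = cost_intervention(spec, rules, discount_rate, cost_scale=cost_scale)
        halys[i] = out.halys_gained
        offsets[i] = out.cost_offsets
        net[i] = c.total_discounted - out.cost_offsets
        ic, _ = compute_icer(net[i], halys[i], wtp)
        if ic is not None and np.isfinite(ic):
            icer[i] = ic

    def summarise(point, arr):
        clean = arr[np.isfinite(arr)]
        if len(clean) == 0:
            return {"point": point, "mean": np.nan, "lo": np.nan, "hi": np.nan}
        return {
            "point": point, "mean": float(np.mean(clean)),
            "lo": float(np.percentile(clean, 2.5)),
            "hi": float(np.percentile(clean, 97.5)),
        }

    outputs = {
        "halys": summarise(det.halys_gained, halys),
        "offsets": summarise(det.cost_offsets, offsets),
        "net_cost": summarise(det_net, net),
        "icer": summarise(det_icer if det_icer is not None else np.nan, icer),
    }
    draws = pd.DataFrame({"halys": halys, "offsets": offsets,
                          "net_cost": net, "icer": icer})
    return MCResult(outputs=outputs, n_iterations=n, seed=seed, draws=draws)


def univariate_sensitivity(bundle: Bundle, spec: InterventionSpec | str,
                           param: str, values,
                           discount_rate: float = 0.03,
                           wtp: float = DEFAULT_WTP,
                           rules: CostingRules | None = None,
                           evaluator: Evaluator | None = None) -> pd.DataFrame:
    """One deterministic run per parameter value, all else at base case."""
    if isinstance(spec, str):
        spec = bundle.get_intervention(spec)
    ev = evaluator or Evaluator(bundle, discount_rate=discount_rate)
    rules = rules or CostingRules()
    rows = []
    for v in values:
        _validate_param_value(param, v)
        ov, cost_scale = _overrides_from_draw(bundle, {param: v})
        out = ev.evaluate(spec, overrides=ov)
        r = ov.get("discount_rate", discount_rate)
        c = cost_intervention(spec, rules, r, cost_scale=cost_scale)
        net = c.total_discounted - out.cost_offsets
        ic, klass = compute_icer(net, out.halys_gained, wtp)
        rows.append({"param": param, "value": v,
                     "halys_gained": out.halys_gained,
                     "cost_offsets": out.cost_offsets,
                     "intervention_cost": c.total_discounted,
                     "net_cost": net, "icer": ic, "dominance_class": klass})
    return pd.DataFrame(rows, columns=[
        "param", "value", "halys_gained", "cost_offsets",
        "intervention_cost", "net_cost", "icer", "dominance_class"])


def _validate_param_value(param: str, v: float) -> None:
    if param == "intervention.uptake" and not 0 <= v <= 1:
        raise ValueError(f"uptake value {v} outside [0, 1]")
    if param == "model.discount_rate" and v < 0:
        raise ValueError(f"discount rate {v} must be >= 0")
    if param == "cost.scale" and v < 0:
        raise ValueError(f"cost scale {v} must be >= 0")


@dataclass
class ThresholdResult:
    threshold: float | None
    icer_at_threshold: float | None
    iterations: int
    diagnostic: str


def threshold_analysis(bundle: Bundle, spec: InterventionSpec | str,
                       param: str, lo: float, hi: float,
                       wtp: float = DEFAULT_WTP, tol: float = 1e-6,
                       discount_rate: float = 0.03,
                       rules: CostingRules | None = None,
                       max_iter: int = 200,
                       evaluator: Evaluator | None = None) -> ThresholdResult:
    """Bisection for the parameter value at which the ICER crosses the
    willingness-to-pay threshold.

    The ICER is treated as -inf while the intervention is dominant.
    Endpoints must bracket the crossing; otherwise a diagnostic result with
    ``threshold=None`` is returned.  Terminates when
    |ICER - wtp| <= tol * wtp.
    """
    if isinstance(spec, str):
        spec = bundle.get_intervention(spec)
    ev = evaluator or Evaluator(bundle, discount_rate=discount_rate)
    rules = rules or CostingRules()

    def icer_at(v: float) -> float:
        ov, cost_scale = _overrides_from_draw(bundle, {param: v})
        out = ev.evaluate(spec, overrides=ov)
        c = cost_intervention(spec, rules,
                              ov.get("discount_rate", discount_rate),
                              cost_scale=cost_scale)
        net = c.total_discounted - out.cost_offsets
        ic, klass = compute_icer(net, out.halys_gained, wtp)
        if klass == DOMINANT:
            return float("-inf")
        if ic is None:
            return float("inf")
        return ic

    f_lo = icer_at(lo) - wtp
    f_hi = icer_at(hi) - wtp
    if f_lo < 0 and f_hi < 0:
        return ThresholdResult(None, None, 2,
                               "no threshold: ICER below willingness-to-pay "
                               "(or dominant) across the entire bracket")
    if f_lo > 0 and f_hi > 0:
        return ThresholdResult(None, None, 2,
                               "no threshold: ICER above willingness-to-pay "
                               "across the entire bracket")
    a, b, fa = lo, hi, f_lo
    it = 0
    mid = 0.5 * (a + b)
    f_mid = float("inf")
    while it < max_iter:
        mid = 0.5 * (a + b)
        f_mid = icer_at(mid) - wtp
        it += 1
        if np.isfinite(f_mid) and abs(f_mid) <= tol * wtp:
            break
        if (f_mid < 0) == (fa < 0):
            a, fa = mid, f_mid
        else:
            b = mid
        if abs(b - a) < 1e-15 * max(1.0, abs(b)):
            break
    return ThresholdResult(mid, f_mid + wtp if np.isfinite(f_mid) else None,
                           it, "converged" if np.isfinite(f_mid)
                           and abs(f_mid) <= tol * wtp else "bracket exhausted")
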
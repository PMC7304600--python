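"""Potential impact fractions (PIFs).

A PIF is the proportional change in disease incidence produced by shifting
a risk-factor distribution:

    PIF = 1 - E_shifted[RR(X)] / E_baseline[RR(X)]

For BMI the distribution-shift method is used: the baseline exposure is a
log-normal BMI distribution, the counterfactual translates that density by
the intervention's BMI shift (mean shifted, spread preserved), and the
relative risk is log-linear per BMI unit above the TMREL,
RR(x) = rr^max(0, x - tmrel).  Expectations are computed by composite
trapezoid integration on [10, 60] kg/m^2 with the TMREL placed exactly on
a node; each expectation is normalised by its own in-support mass so that
clamping the support does not bias the ratio.

For physical activity the relative-risk-shift method is used on the four
ordered activity bands:

    PIF = (sum p0 RR - sum p1 RR) / (sum p0 RR)

Joint BMI x activity effects combine multiplicatively:
1 - (1-pif_bmi)(1-pif_pa).  Negative PIFs (harmful shifts) propagate
unchanged.  PIFs scale incidence only, never case fatality or remission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import DISEASE_IDS
from .effects import RiskDeltas

GRID_LO, GRID_HI = 10.0, 60.0
DEFAULT_NODES = 2001


class PifToleranceError(ValueError):
    """The BMI shift pushes too much probability mass outside the
    integration support."""


def _lognorm_pdf(x: np.ndarray, mu, sigma) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.all(x > 0):  # fast path: the integration grid stays positive
        z = (np.log(x) - mu) / sigma
        return np.exp(-0.5 * z * z) / (x * sigma * np.sqrt(2 * np.pi))
    xs = np.where(x > 0, x, 1.0)  # placeholder keeps log() defined; masked below
    z = (np.log(xs) - mu) / sigma
    return np.where(
        x > 0, np.exp(-0.5 * z * z) / (xs * sigma * np.sqrt(2 * np.pi)), 0.0
    )


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def pif_distribution_shift(bmi_mu: float, bmi_sigma: float, bmi_shift: float,
                           rr_per_unit: float, tmrel: float,
                           grid: np.ndarray | None = None,
                           mass_tol: float = 0.02) -> float:
    """Distribution-shift PIF for a single log-normal stratum.

    ``bmi_mu``/``bmi_sigma`` are the log-scale parameters of the baseline
    BMI distribution, ``bmi_shift`` the signed translation applied to the
    density on the natural scale (negative = beneficial).  Raises
    :class:`PifToleranceError` when the shift moves more than ``mass_tol``
    of the distribution outside the integration support.
    """
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be > 0")
    if bmi_shift == 0.0:
        return 0.0
    if grid is None:
        grid = np.unique(np.concatenate([
            np.linspace(GRID_LO, GRID_HI, DEFAULT_NODES), [tmrel]]))
    w = _trapz_weights(grid)
    rr = np.power(rr_per_unit, np.maximum(0.0, grid - tmrel))

    f0 = _lognorm_pdf(grid, bmi_mu, bmi_sigma)
    f1 = _lognorm_pdf(grid - bmi_shift, bmi_mu, bmi_sigma)
    m0 = float(w @ f0)
    m1 = float(w @ f1)
    if m0 - m1 > mass_tol:
        raise PifToleranceError(
            f"BMI shift {bmi_shift} pushes {m0 - m1:.4f} of probability mass "
            f"outside the [{grid[0]}, {grid[-1]}] integration support"
        )
    e0 = float(w @ (f0 * rr)) / m0
    e1 = float(w @ (f1 * rr)) / m1
    return 1.0 - e1 / e0


def pif_rr_shift(p0, p1, rr_vector) -> float:
    """Relative-risk-shift PIF for categorical exposure."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    rr = np.asarray(rr_vector, dtype=float)
    if not (len(p0) == len(p1) == len(rr)):
        raise ValueError("category proportion and RR vectors must have equal length")
    for name, p in (("p0", p0), ("p1", p1)):
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    if (rr <= 0).any():
        raise ValueError("rr_vector must be positive")
    base = float(p0 @ rr)
    return (base - float(p1 @ rr)) / base


def combine_pifs(pif_a: float | np.ndarray, pif_b: float | np.ndarray):
    """Multiplicative combination of two PIFs acting on the same disease."""
    return 1.0 - (1.0 - np.asarray(pif_a)) * (1.0 - np.asarray(pif_b))


class PifCalculator:
    """Vectorised PIF evaluation across all population strata.

    Baseline densities are evaluated once on a fixed grid; each
    counterfactual evaluation only recomputes the translated densities, so
    repeated calls (Monte Carlo iterations, decaying maintenance profiles)
    stay cheap.
    """

    def __init__(self, population: pd.DataFrame, rr: pd.DataFrame,
                 n_nodes: int = DEFAULT_NODES, mass_tol: float = 0.02):
        self.population = population.reset_index(drop=True)
        self.mu = self.population["bmi_mu"].to_numpy()
        self.sigma = self.population["bmi_sigma"].to_numpy()
        self.p0_pa = self.population[
            ["pa_inactive", "pa_low", "pa_moderate", "pa_high"]].to_numpy()
        self.mass_tol = mass_tol

        tmrels = rr.loc[rr["risk_factor"] == "bmi", "tmrel"].unique()
        self.grid = np.unique(np.concatenate(
            [np.linspace(GRID_LO, GRID_HI, n_nodes), tmrels]))
        self.w = _trapz_weights(self.grid)

        x = self.grid[None, :]
        self.f0 = _lognorm_pdf(x, self.mu[:, None], self.sigma[:, None])
        self.f0w = self.f0 * self.w[None, :]
        self.m0 = self.f0w.sum(axis=1)

        self.rr_bmi: dict[str, tuple[float, float]] = {}
        self.rr_pa: dict[str, np.ndarray] = {}
        for _, row in rr.iterrows():
            if row["risk_factor"] == "bmi":
                self.rr_bmi[row["disease_id"]] = (float(row["rr_per_unit"]),
                                                  float(row["tmrel"]))
            else:
                self.rr_pa[row["disease_id"]] = np.array([
                    row["rr_inactive"], row["rr_low"],
                    row["rr_moderate"], row["rr_high"]], dtype=float)

    def _shifted_densities(self, shifts: np.ndarray, live: np.ndarray):
        """Weighted translated densities for the live strata; shared across
        diseases for a given shift vector."""
        x1 = self.grid[None, :] - shifts[live, None]
        f1 = _lognorm_pdf(x1, self.mu[live, None], self.sigma[live, None])
        f1w = f1 * self.w[None, :]
        m1 = f1w.sum(axis=1)
        lost = self.m0[live] - m1
        if np.any(lost > self.mass_tol):
            worst = float(np.max(lost))
            raise PifToleranceError(
                f"BMI shift moves up to {worst:.4f} of probability mass outside "
                f"the [{self.grid[0]}, {self.grid[-1]}] integration support"
            )
        return f1w, m1

    def disease_rr_curve(self, disease_id: str,
                         rr_override: float | None = None):
        """RR(x) on the grid and the baseline expectation per stratum."""
        rr_point, tmrel = self.rr_bmi[disease_id]
        if rr_override is not None:
            rr_point = rr_override
        rr = np.power(rr_point, np.maximum(0.0, self.grid - tmrel))
        e0 = (self.f0w @ rr) / self.m0
        return rr, e0

    def bmi_pifs(self, disease_id: str, shifts: np.ndarray,
                 rr_override: float | None = None,
                 _cached=None, _curve=None) -> np.ndarray:
        """Distribution-shift PIF per stratum for per-stratum shifts."""
        out = np.zeros_like(shifts, dtype=float)
        live = shifts != 0.0
        if not live.any():
            return out
        rr, e0 = _curve if _curve is not None else self.disease_rr_curve(
            disease_id, rr_override)
        f1w, m1 = self._shifted_densities(shifts, live) if _cached is None else _cached
        e1 = (f1w @ rr) / m1
        out[live] = 1.0 - e1 / e0[live]
        return out

    def pa_pifs(self, disease_id: str, moved_fraction: float,
                targeted: np.ndarray,
                rr_override: np.ndarray | None = None) -> np.ndarray:
        """Relative-risk-shift PIF per stratum when ``moved_fraction`` of
        each non-top band of targeted strata moves one band up."""
        rr = self.rr_pa[disease_id] if rr_override is None else np.asarray(rr_override)
        out = np.zeros(len(self.p0_pa))
        if moved_fraction == 0.0:
            return out
        p0 = self.p0_pa
        p1 = p0.copy()
        m = moved_fraction
        p1[:, :3] = p0[:, :3] * (1 - m)
        p1[:, 1:] = p1[:, 1:] + p0[:, :3] * m
        base = p0 @ rr
        shifted = p1 @ rr
        vals = (base - shifted) / base
        out[targeted] = vals[targeted]
        return out


def pifs_for_intervention(deltas: RiskDeltas, diseases: pd.DataFrame,
                          calculator: PifCalculator,
                          rr_bmi_overrides: dict[str, float] | None = None,
                          rr_pa_overrides: dict[str, np.ndarray] | None = None,
                          pa_related: frozenset | None = None
                          ) -> np.ndarray:
    """PIF table [disease, stratum, year] for one intervention.

    BMI shifts act on all nine diseases via the distribution-shift method;
    activity-band shifts act on the five activity-related diseases via the
    relative-risk-shift method; where both pathways touch a disease they
    combine multiplicatively.  Sedentary-behaviour interventions enter
    through their MET effect only (no independent sedentary pathway).
    """
    rr_bmi_overrides = rr_bmi_overrides or {}
    rr_pa_overrides = rr_pa_overrides or {}
    if pa_related is None:
        meta = diseases.groupby("disease_id").first()
        pa_related = frozenset(meta.index[meta["pa_related"].astype(bool)])
    n_s, n_y = deltas.bmi_shift.shape
    pif = np.zeros((len(DISEASE_IDS), n_s, n_y))

    # group years by identical exposure scale to avoid recomputation
    year_keys: dict[tuple, list[int]] = {}
    for y in range(n_y):
        key = (deltas.bmi_shift[:, y].tobytes(), float(deltas.pa_moved[y]))
        year_keys.setdefault(key, []).append(y)

    curves = {did: calculator.disease_rr_curve(did, rr_bmi_overrides.get(did))
              for did in DISEASE_IDS}
    for (_, moved), years in year_keys.items():
        y0 = years[0]
        shifts = deltas.bmi_shift[:, y0]
        live = shifts != 0.0
        # translated densities depend only on the shift vector: compute once
        # per distinct year group and share across the nine diseases
        cached = calculator._shifted_densities(shifts, live) if live.any() else None
        for d_idx, did in enumerate(DISEASE_IDS):
            p_bmi = calculator.bmi_pifs(did, shifts, _cached=cached,
                                        _curve=curves[did])
            if did in pa_related and moved != 0.0:
                p_pa = calculator.pa_pifs(did, moved, deltas.targeted,
                                          rr_override=rr_pa_overrides.get(did))
                p = combine_pifs(p_bmi, p_pa)
            else:
                p = p_bmi
            for y in years:
                pif[d_idx, :, y] = p
    return pif


def pif_table_to_frame(pif: np.ndarray, population: pd.DataFrame) -> pd.DataFrame:
    """Serialise a PIF array to long form (disease, age, sex, year, pif)."""
    n_d, n_s, n_y = pif.shape
    ages = population["age"].to_numpy()
    sexes = population["sex"].to_numpy()
    recs = []
    for d_idx, did in enumerate(DISEASE_IDS):
        for s in range(n_s):
            col = pif[d_idx, s]
            nz = np.nonzero(col)[0]
            for y in nz:
                recs.append((did, int(ages[s]), sexes[s], int(y), float(col[y])))
    return pd.DataFrame(recs, columns=["disease", "age", "sex", "year", "pif"])
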
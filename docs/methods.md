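# Methods

This note documents the model, its assumptions, the synthetic-data
generator, and the numerical and design choices a user needs to interpret
results. Notation: HALY = health-adjusted life year; PIF = potential
impact fraction; TMREL = theoretical minimum risk exposure level; YLD =
years lived with disability (here an annual morbidity *rate* in [0, 1)).

## Cohort structure and horizon

The model is a proportional multi-state life table: 99 single-year ages
(2–100) × 2 sexes = 198 closed cohorts, each followed in annual cycles
from the 2010 reference year until attained age 100 (no births or
migration). Cohorts are truncated at age 100; the final modelled year
contributes person-years like any other, and remaining life beyond 100 is
dropped identically in baseline and scenario, so incremental outputs are
unaffected to first order. Year 0 (2010) flows are undiscounted; year *t*
flows carry (1 + r)^(−t) with r = 0.03 by default.

## Effect translation

* **Energy intake.** A sustained intake change translates to
  steady-state weight change via a linear coefficient: Δkg = ΔkJ/day ÷ ρ,
  with ρ = 94 kJ/day per kg for adults and 100 for children (configurable
  under `energy_balance:`). This is a deliberate linear stand-in for
  dynamic energy-balance equations; no weight trajectory is modelled —
  the full shift applies from the first model year.
* **Height.** ΔBMI = Δkg / h² using mean height by age and sex; the
  conversion is frozen at the cohort's baseline age.
* **Children.** BMI z-score effects map through the LMS transform
  BMI(z) = M·(1 + L·S·z)^(1/L) (M·e^(S·z) when L = 0), evaluated at
  z₀ = 0. z-score effects are rejected if the target range includes
  adults.
* **Physical activity.** Effects in MET-min/week do two things: (i) move
  an uptake-weighted fraction of each non-top activity band one band
  upward (the band-shift mechanism is a package choice; the step size is
  one band), and (ii) unless `pa_affects_bmi` is disabled, convert to an
  uncompensated energy deficit ΔkJ/day = MET-min/wk × kg × 0.0175 kcal
  × 4.184 / 7 (gross MET-minutes; a `net_mets` flag is reserved) and then
  to a BMI shift. Sedentary-behaviour interventions enter only through
  their MET effect; no independent sedentary pathway exists.
* **Maintenance.** Effect scale over time is `sustained` (1 for life —
  used for all regulatory interventions), `step_to_zero(E)`, or
  `linear_decay(E)` (full effect through implementation, then linear to
  zero at year E). Deltas are exactly zero outside the target strata, at
  zero uptake, and after expiry.

## Potential impact fractions

BMI exposure is log-normal per stratum; the counterfactual *translates*
the density by the BMI shift (mean shifted, spread preserved on the
natural scale). With log-linear RR(x) = rr^max(0, x − TMREL):

PIF = 1 − E₁[RR]/E₀[RR], each expectation a composite-trapezoid integral
on [10, 60] kg/m² over 2001 nodes with the TMREL inserted as an exact
node (no integration bias at the kink), and each normalised by its own
in-support mass so the support clamp cannot bias the ratio. The
translation convention is what makes the no-kink closed form
PIF = 1 − rr^(−δ) hold exactly; the integrator reproduces it to < 1e−4
and agrees with a 10×-resolution run to < 1e−6. A shift that moves more
than 2 % of probability mass off the support raises a tolerance error.

Activity PIFs use the relative-risk-shift form on the four bands
(reference = most active, RR = 1); joint BMI × activity effects combine
multiplicatively, only for the five activity-related diseases. PIFs may
be negative (harmful shifts propagate unchanged) and scale **incidence
only** — never case fatality or remission.

The cohort's exposure distribution is frozen at its baseline (2010) age:
as a cohort ages, its incidence and mortality rates follow attained age,
but its BMI distribution (and hence its PIF for a given shift) does not
drift along the cross-sectional age profile. This keeps the
counterfactual exposure well-defined for a closed cohort and makes a
Monte Carlo iteration ~40× cheaper; the alternative (re-indexing the
exposure to attained age) changes PIFs by second-order amounts relative
to the intervention shift.

## Disease processes and the main life table

Each disease runs a susceptible/prevalent (S/C) sub-lifetable with fixed
within-cycle order — incidence, case fatality, remission — and rates
converted to probabilities via q = 1 − exp(−rate), which keeps
compartments non-negative (a raw small-rate mode exists for didactic
checks). Background mortality, being removed proportionally from S and
C, cancels in the prevalence proportion p = C/(S + C); the process is
therefore run without it and mass conservation holds as
S + C + cumulative disease deaths = 1 (±1e−9). Cohorts start at the
steady-state prevalence obtained by running the same process from age 2
with baseline rates, so a null scenario reproduces the baseline exactly
(the engine runs both through identical code; invariance holds to 1e−12).

Main life table per cohort-year, with attained-age rates:

* mortality m = residual + Σ_d p_d·f_d, where residual = all-cause
  mortality − disease-implied mortality at steady state, floored at zero
  with a logged warning;
* morbidity yld = baseline YLD + Σ_d (p_d − p_d,baseline)·dw_d + child
  term, additive across diseases and capped at 1;
* survivorship by l_{t+1} = l_t·(1 − (1 − e^(−m))), person-years with
  half-cycle correction L = (l_t + l_{t+1})/2;
* HALYs = Σ count·L·(1 − yld)·(1+r)^(−t); healthcare costs count the
  nine modelled diseases only, Σ_d p_d·L·count·cost_d·(1+r)^(−t)
  (unrelated costs in added life years are excluded).

The childhood quality term is a utility decrement of 0.005 per BMI unit
above the age–sex growth-reference median, applied at attained ages 2–17;
only the scenario-minus-baseline difference enters (baseline YLD already
embodies baseline child morbidity). The magnitude is a configurable
stand-in (`child_hrql_coeff`). Scenario runs adjust incidence only, never
case fatality — so the model credits interventions with fewer new cases,
not better prognosis in existing ones.

An independent check: on a two-disease bundle with a single unit cohort,
a 50 000-agent individual-level microsimulation following the same annual
process (common random numbers across scenarios) reproduces the cohort
model's incremental HALYs within three Monte Carlo standard errors
(`tests/test_microsim.py`).

## Economics

Costing takes a limited societal perspective: components accrue to
federal/state/local government, industry or individuals, over explicit
year ranges. Time components are valued at a gender-free wage (default
AUD 40/h) plus salary on-costs (13 % public, 14 % private sector) and
17.5 % leave loading; monetary components are indexed to 2010 with a
health price index (health-related) or GDP index (otherwise). Totals are
discounted; the first-three-year budget figure is reported undiscounted
as a short-term budget-impact indicator.

ICER = net cost / HALYs gained; classes partition the sign/threshold
space: *dominant* (gain + saving, no ICER), *cost-effective*
(ICER < WTP = AUD 50 000/HALY), *not cost-effective*, *dominated*
(loss + cost). Health-neutral cases: positive net cost → not
cost-effective (infinite ICER); otherwise a cost-saving-health-neutral
tag. League tables rank the dominant block by HALYs gained (descending)
before the ICER-sorted remainder; residual ties break alphabetically.
The portfolio summary's "middle 50 %" is defined by rank-dropping —
sort, drop ⌊n/4⌋ from each end, report min and max of the remainder
(for n = 16: ranks 5–12) — which is the definition under which the
packaged fixture reproduces its printed ranges.

Deadweight losses and industry-revenue effects can be supplied as extra
cost components but are excluded from the base case.

## Implementation considerations

Profiles rate strength of evidence for BMI outcomes, evidence on
nutrition/physical-activity outcomes, equity (negative/neutral/positive),
acceptability to public, government and industry, feasibility and
sustainability. Ranking is lexicographic — evidence (BMI), evidence
(PA/diet), equity — with a final sort on the count of high/positive
ratings and alphabetical residual ties. "n/a" evidence sorts below
"low". The tie-breaks beyond the lexicographic keys are package choices;
only positions the stated keys determine unambiguously are asserted in
tests.

## Uncertainty

Monte Carlo (default 2000 iterations) samples every registered parameter
distribution once per iteration and runs baseline and scenario with the
same draw, so shared parameters difference out of incremental outputs.
Default families follow standard health-economics practice: lognormal
for relative risks (median-preserving around the point estimate), beta
for uptake, truncated normal (±4 SE) for effect sizes, gamma for cost
scales and disease costs; all configurable, and degenerate distributions
collapse the pipeline to the deterministic run exactly. Uncertainty
intervals are percentile-based (2.5/97.5). Seeding uses one child
`SeedSequence` stream per distribution, so runs are reproducible across
platforms and adding a distribution does not reshuffle the others.

Univariate sensitivity re-runs the deterministic pipeline over a value
grid. Threshold analysis bisects a parameter (e.g. a cost scale) for the
ICER = WTP crossing, treating dominant regions as ICER = −∞; endpoints
that do not bracket a crossing return a "no threshold" diagnostic. For
cost-scale parameters the ICER is affine in the parameter and the
bisection result matches the algebraic crossing to the requested
tolerance.

## Synthetic data generator

The generator emulates the statistical *shape* of the inputs this model
class assumes — it is not a reconstruction of any real population:

* **BMI** log-normal per stratum (positivity and right skew), mean
  rising from ~16 kg/m² at age 2 to 24 at 18 and 28.5 at 60, CV 0.17,
  with small seeded per-stratum jitter;
* **activity** four ordered bands (inactive/low/moderate/high; midpoints
  100/400/1000/2000 MET-min/wk), adult inactivity drifting up with age;
* **mortality** Gompertz background plus the disease-implied part, so
  the all-cause envelope invariant holds by construction and residual
  mortality is non-negative everywhere;
* **diseases** nine chronic conditions with exponential incidence ramps
  above onset ages, constant case fatality and disability weights, and
  annual per-case costs on realistic 2010-AUD scales; two female-only
  cancers; steady-state prevalence stays below 0.5 at every age;
* **relative risks** per-BMI-unit RRs of 1.03–1.12 above TMREL 21 kg/m²
  and categorical activity RRs up to 1.5 for the inactive band;
* **interventions** sixteen templates mirroring the mix of a realistic
  policy portfolio: nine regulatory (sustained effects) and seven
  program-based (time-limited or decaying effects), four child-targeted,
  two sedentary-behaviour types, with cost components spread across
  sectors.

What the generator does **not** emulate: secular trends in rates, cohort
effects, correlation between BMI and activity within strata, remission,
and real-world effect-size evidence. Tests passing on synthetic bundles
therefore validate the *machinery* (translation, PIFs, life table,
economics, uncertainty), not any substantive claim about a real
population — absolute synthetic HALY/cost outputs are not comparable to
published country-specific results. The packaged printed league-table
fixtures exist precisely to check the economics and ranking layers
against published internal arithmetic, independent of the epidemiology.

## Problem sizes and runtimes

Defaults were chosen so the whole pipeline runs comfortably on a single
CPU: a deterministic 16-intervention study takes a few seconds; 2000
Monte Carlo iterations for all 16 interventions project to roughly 11–13
minutes (the test suite checks this projection from measured
per-iteration cost); the microsimulation oracle uses 50 000 agents on a
two-disease toy bundle and runs in under a second.

## Known limitations

* Linear steady-state energy balance; no compensatory intake or dynamic
  weight trajectories.
* Exposure frozen at baseline age within each cohort (above).
* No lag between exposure change and incidence change.
* Comorbidity handled by additive YLD and additive disease mortality;
  no explicit joint-state accounting.
* Closed cohorts: no population renewal, so population-level totals
  understate what an open-population model would accumulate.
* Injury pathways, productivity impacts and taxation revenue are out of
  scope.
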
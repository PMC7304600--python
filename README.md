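# ace — priority-setting for obesity-prevention policy

`ace` evaluates portfolios of population-level obesity-prevention policies
(food taxes, reformulation, advertising restrictions, school and workplace
programs, …) with a **proportional multi-state life table (PMSLT) Markov
cohort model**, and assembles the results into the league tables and
qualitative rankings that priority-setting studies use.  It is aimed at
health economists and epidemiological modellers who want a transparent,
fully scripted version of this class of analysis; a synthetic-epidemiology
generator supplies internally consistent inputs, so no external data are
needed.

## The model

Each age (2–100) × sex stratum of a reference-year population is followed
as a closed cohort in annual cycles.  An intervention's effect — a change
in energy intake ΔE (kJ/day), physical activity (MET-min/week), BMI, or
child BMI z-score — is translated into a per-stratum BMI shift δ (kg/m²)
via steady-state energy balance (Δkg = ΔE/ρ), mean heights
(ΔBMI = Δkg/h²), or the LMS growth reference
(BMI(z) = M(1 + LSz)^{1/L}), scaled by uptake and a maintenance-of-effect
profile.

The shift perturbs disease incidence through **potential impact
fractions**.  For BMI (log-normal exposure X, log-linear relative risk
RR(x) = rr^{max(0, x − TMREL)}):

    PIF = 1 − E[RR(X + δ)] / E[RR(X)]

computed by trapezoid integration on [10, 60] kg/m²; for physical
activity the categorical relative-risk-shift form
PIF = (Σp₀RR − Σp₁RR)/Σp₀RR over four ordered activity bands; joint
effects combine multiplicatively.  Nine diseases are modelled (all
BMI-related, five also activity-related).  Each disease runs a
sub-lifetable with (1 − PIF)-scaled incidence; prevalence changes feed
back into all-cause mortality and morbidity, and the main lifetable
yields **health-adjusted life years (HALYs)** and healthcare cost offsets,
discounted at 3 % per year.  Net cost per HALY gained against a
no-intervention comparator gives the ICER, judged at AUD 50 000/HALY;
interventions that gain health *and* save money are *dominant* and are
ranked by HALYs gained ahead of the ICER-sorted remainder.

Parameter uncertainty propagates through a common-random-number Monte
Carlo (percentile 95 % uncertainty intervals), with univariate sensitivity
and ICER threshold analyses on top.  A separate module encodes the
qualitative implementation-considerations framework (strength of
evidence, equity, acceptability, feasibility, sustainability) and its
lexicographic ranking.

See [`docs/methods.md`](docs/methods.md) for assumptions, parameter
defaults, and numerical choices.

## Worked example

```python
import ace

bundle = ace.generate_bundle(seed=1)          # synthetic 198-cohort bundle
ace.validate_bundle(bundle)

out = ace.evaluate_intervention(bundle, "ssb_tax_20pct")
print(f"HALYs gained: {out.halys_gained:,.0f}")
print(f"healthcare cost offsets: {out.cost_offsets:,.0f} AUD")
```

prints

```
HALYs gained: 192,604
healthcare cost offsets: 2,848,695,428 AUD
```

i.e. under the synthetic study conditions a sustained 20 % sugary-drink
tax (mean intake effect −30 kJ/day, 55 % uptake) gains about 193 k
discounted HALYs over the lifetime of the modelled population and averts
about AUD 2.8 billion in discounted healthcare costs; with discounted
intervention costs of AUD 134 M it is dominant.  The same pipeline runs
end-to-end from the shell:

```bash
ace generate-data --seed 1 --out bundle/
ace run-study --mode full --bundle bundle/ --out results/
ace league-table            # replay the packaged printed league table
ace considerations          # implementation-considerations ranking
```

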
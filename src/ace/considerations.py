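"""Qualitative implementation-considerations framework.

Beyond the technical cost-effectiveness results, policy prioritisation
weighs strength of evidence, equity impact, acceptability to the public,
government and industry, feasibility, and sustainability — each rated on a
low/medium/high (or negative/neutral/positive) scale.  This module encodes
those profiles and the comparative ranking: lexicographic by strength of
evidence for BMI outcomes, then evidence on nutrition/physical-activity
outcomes, then equity, with a final sort on the number of 'high'/'positive'
ratings; residual ties break alphabetically.  'n/a' evidence ranks below
'low'.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

EVIDENCE_LEVELS = ("n/a", "low", "medium", "high")
EQUITY_LEVELS = ("negative", "neutral", "positive")
RATING_LEVELS = ("low", "medium", "high")

_FIELD_LEVELS = {
    "evidence_bmi": EVIDENCE_LEVELS,
    "evidence_pa_diet": EVIDENCE_LEVELS,
    "equity": EQUITY_LEVELS,
    "accept_public": RATING_LEVELS,
    "accept_government": RATING_LEVELS,
    "accept_industry": RATING_LEVELS,
    "feasibility": RATING_LEVELS,
    "sustainability": RATING_LEVELS,
}

#: ratings counted as favourable in the final tie-break
_FAVOURABLE = frozenset({"high", "positive"})


@dataclass(frozen=True)
class ConsiderationProfile:
    name: str
    evidence_bmi: str
    evidence_pa_diet: str
    equity: str
    accept_public: str
    accept_government: str
    accept_industry: str
    feasibility: str
    sustainability: str

    def __post_init__(self):
        for f in fields(self):
            if f.name == "name":
                continue
            val = getattr(self, f.name).lower()
            object.__setattr__(self, f.name, val)
            if val not in _FIELD_LEVELS[f.name]:
                raise ValueError(
                    f"{f.name}: invalid rating {val!r} "
                    f"(expected one of {_FIELD_LEVELS[f.name]})"
                )

    def favourable_count(self) -> int:
        return sum(
            1 for f in fields(self)
            if f.name != "name" and getattr(self, f.name) in _FAVOURABLE
        )


def _level_rank(field_name: str, value: str) -> int:
    return _FIELD_LEVELS[field_name].index(value)


def rank_considerations(profiles: list[ConsiderationProfile]
                        ) -> list[ConsiderationProfile]:
    """Total ordering of profiles; deterministic for any input."""
    if not profiles:
        raise ValueError("rank_considerations requires at least one profile")
    return sorted(profiles, key=lambda p: (
        -_level_rank("evidence_bmi", p.evidence_bmi),
        -_level_rank("evidence_pa_diet", p.evidence_pa_diet),
        -_level_rank("equity", p.equity),
        -p.favourable_count(),
        p.name,
    ))


def tally(profiles: list[ConsiderationProfile], field_name: str,
          levels) -> int:
    """Number of profiles whose ``field_name`` rating is in ``levels``."""
    if field_name not in _FIELD_LEVELS:
        raise KeyError(f"unknown consideration field {field_name!r}")
    levels = {str(level).lower() for level in levels}
    return sum(1 for p in profiles if getattr(p, field_name) in levels)


def profiles_from_frame(df) -> list[ConsiderationProfile]:
    """Build profiles from a DataFrame with one row per intervention."""
    cols = ["name"] + [f.name for f in fields(ConsiderationProfile)][1:]
    out = []
    for _, row in df.iterrows():
        out.append(ConsiderationProfile(**{c: str(row[c]) for c in cols}))
    return out
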
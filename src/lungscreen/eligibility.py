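"""Inclusion and exclusion criteria for the screening program.

Inclusion: age 50-75 years inclusive, a smoking history of at least
30 pack-years, and either current smoking or having quit within the last
15 years.  Exclusion criteria are boolean flags supplied by the referring
physician (symptoms suggesting malignancy, a chest CT within 12 months,
lung cancer treated within 5 years, a condition preventing the diagnostic
work-up, inability to consent, inability to lie flat / hold breath /
claustrophobia).  All bounds are closed.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Optional, Set

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SmokingStatus",
    "ExclusionFlag",
    "Participant",
    "EligibilityCriteria",
    "EligibilityResult",
    "RosterSummary",
    "assess_eligibility",
    "screen_roster",
]


class SmokingStatus(str, enum.Enum):
    CURRENT = "CURRENT"
    FORMER = "FORMER"
    NEVER = "NEVER"


class ExclusionFlag(str, enum.Enum):
    SYMPTOMS_SUGGESTING_MALIGNANCY = "SYMPTOMS_SUGGESTING_MALIGNANCY"
    CHEST_CT_WITHIN_12_MONTHS = "CHEST_CT_WITHIN_12_MONTHS"
    LUNG_CANCER_TREATED_WITHIN_5_YEARS = "LUNG_CANCER_TREATED_WITHIN_5_YEARS"
    CONDITION_PREVENTS_DIAGNOSTICS = "CONDITION_PREVENTS_DIAGNOSTICS"
    CANNOT_CONSENT = "CANNOT_CONSENT"
    CANNOT_LIE_FLAT_HOLD_BREATH_OR_CLAUSTROPHOBIA = (
        "CANNOT_LIE_FLAT_HOLD_BREATH_OR_CLAUSTROPHOBIA"
    )


class Participant(BaseModel):
    """A screening candidate as seen at eligibility assessment."""

    participant_id: str
    age_years: int = Field(ge=0)
    smoking_status: SmokingStatus
    pack_years: float = Field(ge=0)
    years_since_quit: Optional[float] = Field(default=None, ge=0)
    exclusion_flags: Set[ExclusionFlag] = Field(default_factory=set)

    @model_validator(mode="after")
    def _check_history(self) -> "Participant":
        if (self.smoking_status is SmokingStatus.FORMER) != (self.years_since_quit is not None):
            raise ValueError("years_since_quit must be present exactly for FORMER smokers")
        if self.smoking_status is SmokingStatus.NEVER and self.pack_years > 0:
            raise ValueError(
                f"participant {self.participant_id!r}: NEVER smoker with positive pack-years"
            )
        return self


class EligibilityCriteria(BaseModel):
    """Program bounds; defaults are the national criteria, all closed."""

    min_age_years: int = 50
    max_age_years: int = 75
    min_pack_years: float = 30.0
    max_years_since_quit: float = 15.0


class EligibilityResult(BaseModel):
    eligible: bool
    failed_criteria: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "EligibilityResult":
        if self.eligible != (not self.failed_criteria):
            raise ValueError("eligible must mean an empty failed_criteria list")
        return self


class RosterSummary(BaseModel):
    n_total: int
    n_eligible: int
    n_ineligible: int
    failed_criterion_counts: dict[str, int] = Field(default_factory=dict)


def assess_eligibility(
    p: Participant, criteria: Optional[EligibilityCriteria] = None
) -> EligibilityResult:
    """Evaluate one candidate against all inclusion and exclusion criteria.

    Every violated criterion is listed, not just the first; a candidate is
    eligible exactly when the list is empty.
    """
    c = criteria or EligibilityCriteria()
    failed: list[str] = []
    if p.age_years < c.min_age_years:
        failed.append("AGE_BELOW_MIN")
    elif p.age_years > c.max_age_years:
        failed.append("AGE_ABOVE_MAX")
    if p.pack_years < c.min_pack_years:
        failed.append("INSUFFICIENT_PACK_YEARS")
    if p.smoking_status is SmokingStatus.NEVER:
        failed.append("NEVER_SMOKER")
    elif p.smoking_status is SmokingStatus.FORMER:
        assert p.years_since_quit is not None  # model invariant
        if p.years_since_quit > c.max_years_since_quit:
            failed.append("QUIT_TOO_LONG_AGO")
    failed.extend(sorted(flag.value for flag in p.exclusion_flags))
    return EligibilityResult(eligible=not failed, failed_criteria=failed)


def screen_roster(
    roster: Iterable[Participant], criteria: Optional[EligibilityCriteria] = None
) -> RosterSummary:
    """Evaluate a roster and tally eligibility and per-criterion failures."""
    n_total = n_eligible = 0
    tally: Counter[str] = Counter()
    for p in roster:
        n_total += 1
        result = assess_eligibility(p, criteria)
        if result.eligible:
            n_eligible += 1
        tally.update(result.failed_criteria)
    return RosterSummary(
        n_total=n_total,
        n_eligible=n_eligible,
        n_ineligible=n_total - n_eligible,
        failed_criterion_counts=dict(tally),
    )
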
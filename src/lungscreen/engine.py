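"""Decision rules of the volumetric nodule-management protocol.

Each screening round type has its own rule column:

* **Baseline** — severity is driven by the size of the largest solid nodule
  (or solid component of a part-solid nodule); non-solid nodules of any size
  and sub-6.5 mm solid nodules return to annual screening; endobronchial
  nodules get a 1-month recall; a solid nodule of 15.5 mm / 2000 mm3 or more
  is a positive screen and is referred.
* **Annual / biennial repeat** — only NEW or GROWING nodules can raise the
  result above negative; bands at 3.0 mm / 20 mm3 and 6.5 mm / 150 mm3 map
  to 12-, 6- and 1-month recalls; a persistent endobronchial nodule and a
  non-solid nodule that doubled within a year with an emergent solid
  component are positive.
* **Interim follow-up** — severity is driven by the volume doubling time of
  the nodule that triggered the recall: VDT < 400 d is positive, 400-600 d
  gets a 6-month recall (positive when the nodule is larger than
  15 mm / 2000 mm3), VDT >= 600 d returns to the annual schedule.

Every classification carries an auditable ``rule_code`` (one per table cell,
see :data:`RULES`) and a trace of every rule that fired on the scan.

Boundary conventions follow the printed wording exactly: ">=" thresholds are
closed below, "<" open above; the VDT semi-positive band is [400, 600) with
600 d itself in the annual-return cell.  When a nodule carries both a
measured volume and a diameter, the volume criterion governs (the program is
volumetric by design); this is recorded in the trace.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from pydantic import BaseModel, model_validator

from .nodule import (
    NOT_GROWING,
    GrowthAssessment,
    GrowthClass,
    NoduleObservation,
    NoduleType,
    ProtocolThresholds,
    RoundType,
    ScanContext,
    UnsizedNoduleError,
)

__all__ = [
    "Category",
    "Action",
    "ScanClassification",
    "RULES",
    "classify_baseline",
    "classify_repeat",
    "classify_followup",
    "classify_scan",
    "next_round_type",
]


class Category(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    SEMI_POSITIVE = "SEMI_POSITIVE"
    POSITIVE = "POSITIVE"


class Action(str, enum.Enum):
    REPEAT_LDCT = "REPEAT_LDCT"
    REFER_NODULE_CLINIC = "REFER_NODULE_CLINIC"


_SEVERITY = {Category.NEGATIVE: 0, Category.SEMI_POSITIVE: 1, Category.POSITIVE: 2}

#: Cross-reference of every rule code to the protocol-table cell it encodes.
RULES: Mapping[str, str] = {
    "BL.a1": "Baseline: no non-calcified nodules -> annual screening in 12 months",
    "BL.b1": "Baseline: only non-solid nodules, any size -> 12 months",
    "BL.b2": "Baseline: largest solid NCN or solid component < 6.5 mm (< 150 mm3) -> 12 months",
    "BL.b3": "Baseline: solid NCN or solid component >= 6.5 mm (>= 150 mm3) but < 15.5 mm (2000 mm3) -> 3 months",
    "BL.b4": "Baseline: endobronchial solid nodule of any size -> 1 month",
    "BL.c1": "Baseline: solid NCN or solid component >= 15.5 mm (>= 2000 mm3) -> referral",
    "RPT.a1": "Repeat: no new or growing nodules -> next repeat in 24 months",
    "RPT.b1": "Repeat: only new or slowly growing non-solid NCNs -> 12 months",
    "RPT.b2": "Repeat: new/growing solid NCN or solid component < 3.0 mm (< 20 mm3) -> 12 months",
    "RPT.b3": "Repeat: new/growing solid NCN or solid component 3.0-6.5 mm (20-150 mm3) -> 6 months",
    "RPT.b4": "Repeat: new/growing solid NCN or solid component >= 6.5 mm (>= 150 mm3) -> 1 month, consider antibiotics",
    "RPT.b5": "Repeat: new endobronchial nodule of any size -> 1 month",
    "RPT.c1": "Repeat: non-solid nodule doubled in volume within 1 year with an emergent solid component -> referral",
    "RPT.c1.watch": "Repeat: non-solid nodule doubled within 1 year WITHOUT a solid component (advisory trace only)",
    "RPT.c2": "Repeat: persistent endobronchial nodule after 1 month -> referral",
    "FU.a1": "Follow-up: nodule resolved -> next repeat in 24 months",
    "FU.b1": "Follow-up: VDT >= 600 days -> back to annual schedule, 12 months",
    "FU.b2": "Follow-up: VDT 400-600 days -> repeat in 6 months",
    "FU.c1": "Follow-up: VDT < 400 days -> referral",
    "FU.c2": "Follow-up: persistent endobronchial nodule -> referral",
    "FU.c3": "Follow-up: VDT 400-600 days and nodule larger than 15 mm (2000 mm3) -> referral",
    "VOL.governs": "Measured volume and diameter disagree across a threshold; volume governs (advisory trace only)",
}

#: Trace-only codes that never set the scan's rule_code.
_ADVISORY = {"RPT.c1.watch", "VOL.governs"}


class ScanClassification(BaseModel):
    """Result of classifying one scan: category, action and audit trail."""

    category: Category
    action: Action
    interval_months: Optional[int] = None
    consider_antibiotics: bool = False
    rule_code: str
    driving_nodule_id: Optional[str] = None
    trace: Sequence[Tuple[Optional[str], str]] = ()

    @model_validator(mode="after")
    def _check_consistency(self) -> "ScanClassification":
        if (self.category is Category.POSITIVE) != (self.action is Action.REFER_NODULE_CLINIC):
            raise ValueError("POSITIVE scans and only POSITIVE scans are referred")
        if (self.interval_months is not None) != (self.action is Action.REPEAT_LDCT):
            raise ValueError("interval_months is present exactly for REPEAT_LDCT")
        if self.interval_months is not None and self.interval_months not in {1, 3, 6, 12, 24}:
            raise ValueError(f"invalid recall interval: {self.interval_months}")
        if self.rule_code not in RULES:
            raise ValueError(f"unknown rule code: {self.rule_code}")
        return self


@dataclass(frozen=True)
class _Contribution:
    """One rule that fired for one nodule."""

    nodule_id: Optional[str]
    code: str
    category: Category
    interval_months: Optional[int]  # None for referrals and advisory entries
    antibiotics: bool = False
    advisory: bool = False


def _solid_size(
    obs: NoduleObservation,
) -> Tuple[Optional[float], Optional[float]]:
    """(diameter, volume) that the solid-size rules should judge.

    For part-solid nodules this is the solid component; if no component
    measurement was recorded the overall size is used as a conservative
    fallback.
    """
    if obs.nodule_type is NoduleType.PART_SOLID and (
        obs.solid_comp_diameter_mm is not None or obs.solid_comp_volume_mm3 is not None
    ):
        return obs.solid_comp_diameter_mm, obs.solid_comp_volume_mm3
    return obs.avg_diameter_mm, obs.volume_mm3


def _at_least(
    diameter_mm: Optional[float],
    volume_mm3: Optional[float],
    thr_mm: float,
    thr_mm3: float,
    nodule_id: str,
) -> Tuple[bool, bool]:
    """Is the size at or above the (diameter, volume) threshold pair?

    Returns ``(verdict, volume_governed)`` where the second element flags a
    measured volume overriding a disagreeing diameter.  The two printed
    thresholds are independent criteria; when a measured volume is present it
    governs.
    """
    if volume_mm3 is not None:
        verdict = volume_mm3 >= thr_mm3
        disagrees = diameter_mm is not None and (diameter_mm >= thr_mm) != verdict
        return verdict, disagrees
    if diameter_mm is not None:
        return diameter_mm >= thr_mm, False
    raise UnsizedNoduleError(f"nodule {nodule_id!r} has no usable size measurement")


def _size_contributions(
    obs: NoduleObservation,
    thresholds: ProtocolThresholds,
    *,
    baseline: bool,
) -> Iterable[_Contribution]:
    """Band a solid nodule (or solid component) for the baseline or repeat column."""
    d, v = _solid_size(obs)
    if baseline:
        positive, gov1 = _at_least(
            d, v, thresholds.positive_solid_mm, thresholds.positive_solid_mm3, obs.nodule_id
        )
        if positive:
            yield _Contribution(obs.nodule_id, "BL.c1", Category.POSITIVE, None)
        else:
            semi, gov2 = _at_least(
                d, v, thresholds.semi_solid_mm, thresholds.semi_solid_mm3, obs.nodule_id
            )
            gov1 = gov1 or gov2
            if semi:
                yield _Contribution(
                    obs.nodule_id, "BL.b3", Category.SEMI_POSITIVE,
                    thresholds.baseline_recall_months,
                )
            else:
                yield _Contribution(
                    obs.nodule_id, "BL.b2", Category.SEMI_POSITIVE, thresholds.annual_months
                )
        if gov1:
            yield _Contribution(obs.nodule_id, "VOL.governs", Category.NEGATIVE, None, advisory=True)
    else:
        large, gov1 = _at_least(
            d, v, thresholds.semi_solid_mm, thresholds.semi_solid_mm3, obs.nodule_id
        )
        if large:
            yield _Contribution(
                obs.nodule_id, "RPT.b4", Category.SEMI_POSITIVE,
                thresholds.immediate_recall_months, antibiotics=True,
            )
        else:
            medium, gov2 = _at_least(
                d, v, thresholds.small_solid_mm, thresholds.small_solid_mm3, obs.nodule_id
            )
            gov1 = gov1 or gov2
            if medium:
                yield _Contribution(
                    obs.nodule_id, "RPT.b3", Category.SEMI_POSITIVE,
                    thresholds.short_recall_months,
                )
            else:
                yield _Contribution(
                    obs.nodule_id, "RPT.b2", Category.SEMI_POSITIVE, thresholds.annual_months
                )
        if gov1:
            yield _Contribution(obs.nodule_id, "VOL.governs", Category.NEGATIVE, None, advisory=True)


def _aggregate(
    contributions: Sequence[_Contribution],
    default_code: str,
    default_interval: int,
) -> ScanClassification:
    """Combine per-nodule rule hits into one scan result.

    Category is the maximum severity across nodules; among repeat
    recommendations the shortest interval wins; a referral dominates
    everything.  Advisory entries appear in the trace only.
    """
    trace = [(c.nodule_id, c.code) for c in contributions]
    actionable = [c for c in contributions if not c.advisory]
    antibiotics = any(c.antibiotics for c in actionable)
    if not actionable:
        return ScanClassification(
            category=Category.NEGATIVE,
            action=Action.REPEAT_LDCT,
            interval_months=default_interval,
            consider_antibiotics=antibiotics,
            rule_code=default_code,
            driving_nodule_id=None,
            trace=trace + [(None, default_code)],
        )
    top = max(_SEVERITY[c.category] for c in actionable)
    if top == _SEVERITY[Category.POSITIVE]:
        driving = next(c for c in actionable if c.category is Category.POSITIVE)
        return ScanClassification(
            category=Category.POSITIVE,
            action=Action.REFER_NODULE_CLINIC,
            interval_months=None,
            consider_antibiotics=antibiotics,
            rule_code=driving.code,
            driving_nodule_id=driving.nodule_id,
            trace=trace,
        )
    # Shortest recall wins; severity breaks ties so a semi-positive rule is
    # reported over a negative-cell rule sharing its interval.
    driving = min(
        actionable,
        key=lambda c: (c.interval_months, -_SEVERITY[c.category]),
    )
    return ScanClassification(
        category=Category(max(actionable, key=lambda c: _SEVERITY[c.category]).category),
        action=Action.REPEAT_LDCT,
        interval_months=driving.interval_months,
        consider_antibiotics=antibiotics,
        rule_code=driving.code,
        driving_nodule_id=driving.nodule_id,
        trace=trace,
    )


def classify_baseline(
    observations: Sequence[NoduleObservation],
    thresholds: Optional[ProtocolThresholds] = None,
) -> ScanClassification:
    """Apply the baseline column to a scan's nodule observations.

    An empty list (or calcified nodules only) is a negative screen with a
    12-month return.
    """
    thresholds = thresholds or ProtocolThresholds()
    contributions: list[_Contribution] = []
    for obs in observations:
        if obs.nodule_type is NoduleType.CALCIFIED or obs.is_resolved:
            continue
        if obs.nodule_type is NoduleType.ENDOBRONCHIAL:
            contributions.append(
                _Contribution(
                    obs.nodule_id, "BL.b4", Category.SEMI_POSITIVE,
                    thresholds.immediate_recall_months,
                )
            )
        elif obs.nodule_type is NoduleType.NON_SOLID:
            contributions.append(
                _Contribution(
                    obs.nodule_id, "BL.b1", Category.SEMI_POSITIVE, thresholds.annual_months
                )
            )
        else:  # SOLID or PART_SOLID: judged by (solid component) size
            contributions.extend(
                _size_contributions(obs, thresholds, baseline=True)
            )
    return _aggregate(contributions, "BL.a1", thresholds.annual_months)


def _is_new_or_growing(obs: NoduleObservation, growth: Optional[GrowthAssessment]) -> bool:
    if obs.is_new or (growth is not None and growth.growth_class is GrowthClass.NEW):
        return True
    return growth is not None and growth.growth_class is GrowthClass.GROWING


def classify_repeat(
    observations_with_growth: Sequence[
        Tuple[NoduleObservation, Optional[GrowthAssessment]]
    ],
    thresholds: Optional[ProtocolThresholds] = None,
) -> ScanClassification:
    """Apply the annual/biennial repeat column.

    Only NEW or GROWING nodules can raise the result above negative; stable,
    shrinking or slowly growing solid nodules contribute nothing.  Every
    pre-existing (not new, not resolved) nodule must carry a growth
    assessment.
    """
    thresholds = thresholds or ProtocolThresholds()
    contributions: list[_Contribution] = []
    for obs, growth in observations_with_growth:
        if obs.nodule_type is NoduleType.CALCIFIED or obs.is_resolved:
            continue
        if not obs.is_new and growth is None:
            raise ValueError(
                f"nodule {obs.nodule_id!r}: pre-existing nodule lacks a growth assessment"
            )
        if obs.nodule_type is NoduleType.ENDOBRONCHIAL:
            if obs.is_new or (growth is not None and growth.growth_class is GrowthClass.NEW):
                contributions.append(
                    _Contribution(
                        obs.nodule_id, "RPT.b5", Category.SEMI_POSITIVE,
                        thresholds.immediate_recall_months,
                    )
                )
            else:  # persisted from the prior scan
                contributions.append(
                    _Contribution(obs.nodule_id, "RPT.c2", Category.POSITIVE, None)
                )
            continue
        doubled_within_year = (
            growth is not None
            and isinstance(growth.vdt_days, (int, float))
            and growth.vdt_days <= 365.0
        )
        if obs.nodule_type is NoduleType.PART_SOLID and doubled_within_year:
            # Doubling within a year with a solid component present: the
            # emergent-solid-component referral rule.
            contributions.append(
                _Contribution(obs.nodule_id, "RPT.c1", Category.POSITIVE, None)
            )
            continue
        if obs.nodule_type is NoduleType.NON_SOLID and doubled_within_year:
            # Doubling without a solid component is not positive under the
            # printed rule; leave an advisory marker in the trace.
            contributions.append(
                _Contribution(
                    obs.nodule_id, "RPT.c1.watch", Category.NEGATIVE, None, advisory=True
                )
            )
        if not _is_new_or_growing(obs, growth):
            if (
                obs.nodule_type is NoduleType.NON_SOLID
                and growth is not None
                and growth.growth_class is GrowthClass.SLOWLY_GROWING
            ):
                contributions.append(
                    _Contribution(
                        obs.nodule_id, "RPT.b1", Category.SEMI_POSITIVE,
                        thresholds.annual_months,
                    )
                )
            continue
        if obs.nodule_type is NoduleType.NON_SOLID:
            contributions.append(
                _Contribution(
                    obs.nodule_id, "RPT.b1", Category.SEMI_POSITIVE, thresholds.annual_months
                )
            )
        else:  # SOLID or PART_SOLID
            contributions.extend(
                _size_contributions(obs, thresholds, baseline=False)
            )
    return _aggregate(contributions, "RPT.a1", thresholds.biennial_months)


def classify_followup(
    observations_with_growth: Sequence[
        Tuple[NoduleObservation, Optional[GrowthAssessment]]
    ],
    thresholds: Optional[ProtocolThresholds] = None,
) -> ScanClassification:
    """Apply the interim follow-up column (VDT bands).

    VDT < 400 d is positive; [400, 600) d earns a 6-month recall unless the
    nodule is larger than 15 mm / 2000 mm3 (then positive); VDT >= 600 d (or
    no growth at all) returns the participant to the annual schedule; a
    resolved nodule is negative with a 24-month return; a persistent
    endobronchial nodule is positive.
    """
    thresholds = thresholds or ProtocolThresholds()
    contributions: list[_Contribution] = []
    for obs, growth in observations_with_growth:
        if obs.nodule_type is NoduleType.CALCIFIED:
            continue
        if obs.is_new or (growth is not None and growth.growth_class is GrowthClass.NEW):
            # A nodule first seen on an interim scan has no VDT; it is handled
            # with the repeat-column new-nodule rules.
            if obs.nodule_type is NoduleType.ENDOBRONCHIAL:
                contributions.append(
                    _Contribution(
                        obs.nodule_id, "RPT.b5", Category.SEMI_POSITIVE,
                        thresholds.immediate_recall_months,
                    )
                )
            elif obs.nodule_type is NoduleType.NON_SOLID:
                contributions.append(
                    _Contribution(
                        obs.nodule_id, "RPT.b1", Category.SEMI_POSITIVE,
                        thresholds.annual_months,
                    )
                )
            else:
                contributions.extend(_size_contributions(obs, thresholds, baseline=False))
            continue
        if obs.is_resolved or (growth is not None and growth.growth_class is GrowthClass.RESOLVED):
            contributions.append(
                _Contribution(
                    obs.nodule_id, "FU.a1", Category.NEGATIVE, thresholds.biennial_months
                )
            )
            continue
        if obs.nodule_type is NoduleType.ENDOBRONCHIAL:
            contributions.append(
                _Contribution(obs.nodule_id, "FU.c2", Category.POSITIVE, None)
            )
            continue
        if growth is None or growth.vdt_days is None:
            raise ValueError(
                f"nodule {obs.nodule_id!r}: follow-up classification requires a VDT"
            )
        vdt = growth.vdt_days
        if vdt == NOT_GROWING or (
            isinstance(vdt, (int, float)) and vdt >= thresholds.vdt_semi_upper_days
        ):
            contributions.append(
                _Contribution(
                    obs.nodule_id, "FU.b1", Category.SEMI_POSITIVE, thresholds.annual_months
                )
            )
        elif vdt < thresholds.vdt_positive_days:
            contributions.append(
                _Contribution(obs.nodule_id, "FU.c1", Category.POSITIVE, None)
            )
        else:  # 400 <= vdt < 600
            d, v = _solid_size(obs)
            if v is not None:
                large = v > thresholds.followup_large_mm3
            elif d is not None:
                large = d > thresholds.followup_large_mm
            else:
                raise UnsizedNoduleError(
                    f"nodule {obs.nodule_id!r} has no usable size measurement"
                )
            if large:
                contributions.append(
                    _Contribution(obs.nodule_id, "FU.c3", Category.POSITIVE, None)
                )
            else:
                contributions.append(
                    _Contribution(
                        obs.nodule_id, "FU.b2", Category.SEMI_POSITIVE,
                        thresholds.short_recall_months,
                    )
                )
    return _aggregate(contributions, "FU.a1", thresholds.biennial_months)


def classify_scan(
    context: ScanContext,
    observations: Sequence[NoduleObservation],
    growth: Optional[Mapping[str, GrowthAssessment]] = None,
    thresholds: Optional[ProtocolThresholds] = None,
) -> ScanClassification:
    """Dispatch a scan to the rule column matching its round type.

    ``growth`` maps nodule_id to the nodule's growth assessment; it is
    ignored at baseline and required (for pre-existing nodules) otherwise.
    """
    growth = growth or {}
    if context.round_type is RoundType.BASELINE:
        return classify_baseline(observations, thresholds)
    pairs = [(obs, growth.get(obs.nodule_id)) for obs in observations]
    if context.round_type in (RoundType.ANNUAL_REPEAT, RoundType.BIENNIAL_REPEAT):
        return classify_repeat(pairs, thresholds)
    if context.round_type is RoundType.INTERIM_FOLLOWUP:
        return classify_followup(pairs, thresholds)
    raise ValueError(f"unknown round type: {context.round_type!r}")


def next_round_type(
    classification: ScanClassification, context: ScanContext
) -> Optional[RoundType]:
    """Schedule the next round implied by a classification.

    A 24-month negative result moves the participant to biennial screening
    (the biennial rule: negative baseline and regular repeats with no new or
    growing nodules); 12-month results stay on the annual schedule; shorter
    recalls are interim follow-ups; a referral ends scheduled screening
    (returns ``None``).
    """
    if classification.action is Action.REFER_NODULE_CLINIC:
        return None
    months = classification.interval_months
    if months == 24:
        return RoundType.BIENNIAL_REPEAT
    if months == 12:
        return RoundType.ANNUAL_REPEAT
    return RoundType.INTERIM_FOLLOWUP
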
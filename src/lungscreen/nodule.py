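"""Domain types and growth mathematics for screening-detected pulmonary nodules.

This module holds the vocabulary shared by the whole package: what a nodule
observation is, what a screening round is, and the small amount of geometry
(sphere volumetry, average diameter) and kinetics (volume doubling time,
growth classification) the management rules are built on.

Units are fixed throughout the package: lengths in millimetres, volumes in
cubic millimetres, durations in days, recall intervals in months.  No unit
auto-detection is performed.
"""

from __future__ import annotations

import enum
import math
from datetime import date
from typing import Final, Literal, Optional, Union

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "NOT_GROWING",
    "NotGrowingType",
    "VdtDays",
    "NoduleType",
    "RoundType",
    "GrowthClass",
    "NoduleObservation",
    "ScanContext",
    "GrowthAssessment",
    "ProtocolThresholds",
    "GrowthConfig",
    "UnsizedNoduleError",
    "sphere_volume",
    "equivalent_diameter",
    "average_diameter",
    "compute_vdt",
    "assess_growth",
]

#: Sentinel for a nodule whose volume did not increase between two scans.
#: A string (rather than ``inf``) so it serialises portably to JSON/CSV.
NOT_GROWING: Final = "NOT_GROWING"

NotGrowingType = Literal["NOT_GROWING"]
VdtDays = Union[float, NotGrowingType]


class NoduleType(str, enum.Enum):
    """Attenuation / location class of a nodule.

    Calcified nodules are considered benign and never drive management;
    non-solid is the ground-glass class; part-solid nodules are managed by
    the size of their solid component.
    """

    SOLID = "SOLID"
    PART_SOLID = "PART_SOLID"
    NON_SOLID = "NON_SOLID"
    ENDOBRONCHIAL = "ENDOBRONCHIAL"
    CALCIFIED = "CALCIFIED"


class RoundType(str, enum.Enum):
    """Which screening round a scan belongs to."""

    BASELINE = "BASELINE"
    ANNUAL_REPEAT = "ANNUAL_REPEAT"
    BIENNIAL_REPEAT = "BIENNIAL_REPEAT"
    INTERIM_FOLLOWUP = "INTERIM_FOLLOWUP"


class GrowthClass(str, enum.Enum):
    """Qualitative change of a nodule between two scans."""

    NEW = "NEW"
    GROWING = "GROWING"
    SLOWLY_GROWING = "SLOWLY_GROWING"
    STABLE = "STABLE"
    SHRINKING = "SHRINKING"
    RESOLVED = "RESOLVED"


class UnsizedNoduleError(ValueError):
    """Raised when a rule needs a nodule size and none is available."""


class NoduleObservation(BaseModel):
    """One nodule as measured on one scan.

    At least one of ``avg_diameter_mm`` / ``volume_mm3`` must be present
    unless the nodule has resolved.  Solid-component fields are only
    meaningful (and only allowed) for part-solid nodules.
    """

    nodule_id: str
    nodule_type: NoduleType
    avg_diameter_mm: Optional[float] = Field(default=None, ge=0)
    volume_mm3: Optional[float] = Field(default=None, ge=0)
    solid_comp_diameter_mm: Optional[float] = Field(default=None, ge=0)
    solid_comp_volume_mm3: Optional[float] = Field(default=None, ge=0)
    is_new: bool = False
    is_resolved: bool = False
    location: str = ""

    @model_validator(mode="after")
    def _check_invariants(self) -> "NoduleObservation":
        if self.is_new and self.is_resolved:
            raise ValueError("a nodule cannot be both new and resolved")
        if not self.is_resolved and self.avg_diameter_mm is None and self.volume_mm3 is None:
            raise ValueError(
                f"nodule {self.nodule_id!r}: at least one of avg_diameter_mm / "
                "volume_mm3 is required unless the nodule is resolved"
            )
        if self.nodule_type is not NoduleType.PART_SOLID and (
            self.solid_comp_diameter_mm is not None or self.solid_comp_volume_mm3 is not None
        ):
            raise ValueError(
                f"nodule {self.nodule_id!r}: solid-component fields are only "
                "valid for PART_SOLID nodules"
            )
        return self


class ScanContext(BaseModel):
    """Metadata for one scan: round type, date, spacing, dose."""

    round_type: RoundType
    scan_date: date = date(2025, 1, 1)
    days_since_prior: Optional[float] = Field(default=None, gt=0)
    effective_dose_mSv: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_spacing(self) -> "ScanContext":
        if self.round_type is not RoundType.BASELINE and self.days_since_prior is None:
            raise ValueError("days_since_prior is required for non-baseline rounds")
        return self


class GrowthConfig(BaseModel):
    """Operational definition of "growing" (the protocol table does not give one).

    A nodule is GROWING when its volume increased by at least
    ``min_relative_volume_increase`` between the paired scans; smaller strict
    increases are SLOWLY_GROWING.  ``slow_growth_vdt_days`` marks the doubling
    time above which growth of a non-solid nodule is considered indolent.
    """

    min_relative_volume_increase: float = Field(default=0.30, ge=0, lt=1)
    slow_growth_vdt_days: float = Field(default=600.0, gt=0)


class ProtocolThresholds(BaseModel):
    """Every numeric constant of the management table in one overridable place.

    The diameter and volume thresholds are deliberately *independent* criteria
    exactly as the protocol prints them (6.5 mm is paired with 150 mm3 and
    15.5 mm with 2000 mm3 even though the exact sphere volumes are 143.8 and
    1949.8 mm3); neither is ever recomputed from the other.  The follow-up
    column uses its own printed "larger than 15 mm (2000 mm3)" bound.
    """

    small_solid_mm: float = 3.0
    small_solid_mm3: float = 20.0
    semi_solid_mm: float = 6.5
    semi_solid_mm3: float = 150.0
    positive_solid_mm: float = 15.5
    positive_solid_mm3: float = 2000.0
    followup_large_mm: float = 15.0
    followup_large_mm3: float = 2000.0
    vdt_positive_days: float = 400.0
    vdt_semi_upper_days: float = 600.0
    # Recall intervals, months.
    immediate_recall_months: int = 1
    baseline_recall_months: int = 3
    short_recall_months: int = 6
    annual_months: int = 12
    biennial_months: int = 24

    @model_validator(mode="after")
    def _check_ordering(self) -> "ProtocolThresholds":
        if not (self.small_solid_mm < self.semi_solid_mm < self.positive_solid_mm):
            raise ValueError("diameter thresholds must satisfy small < semi < positive")
        if not (self.small_solid_mm3 < self.semi_solid_mm3 < self.positive_solid_mm3):
            raise ValueError("volume thresholds must satisfy small < semi < positive")
        if not self.vdt_positive_days < self.vdt_semi_upper_days:
            raise ValueError("vdt_positive_days must be below vdt_semi_upper_days")
        return self


class GrowthAssessment(BaseModel):
    """Change metrics for one nodule between two paired scans."""

    prior_volume_mm3: Optional[float] = Field(default=None, gt=0)
    current_volume_mm3: Optional[float] = Field(default=None, ge=0)
    delta_days: Optional[float] = Field(default=None, gt=0)
    vdt_days: Optional[VdtDays] = None
    growth_class: GrowthClass

    @model_validator(mode="after")
    def _check_vdt(self) -> "GrowthAssessment":
        if (
            self.prior_volume_mm3 is not None
            and self.current_volume_mm3 is not None
            and self.current_volume_mm3 > self.prior_volume_mm3
        ):
            if not (isinstance(self.vdt_days, (int, float)) and self.vdt_days > 0):
                raise ValueError("vdt_days must be a positive number when volume increased")
        elif (
            self.prior_volume_mm3 is not None
            and self.current_volume_mm3 is not None
            and self.vdt_days != NOT_GROWING
        ):
            raise ValueError("vdt_days must be NOT_GROWING when volume did not increase")
        return self


# --------------------------------------------------------------------------
# Geometry and kinetics
# --------------------------------------------------------------------------

def sphere_volume(avg_diameter_mm: float) -> float:
    """Volume (mm3) of a sphere of the given diameter: pi * d**3 / 6.

    >>> round(sphere_volume(6.5), 2)
    143.79
    """
    if avg_diameter_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {avg_diameter_mm}")
    return math.pi * avg_diameter_mm**3 / 6.0


def equivalent_diameter(volume_mm3: float) -> float:
    """Diameter (mm) of the sphere with the given volume; inverse of sphere_volume."""
    if volume_mm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_mm3}")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


def average_diameter(long_axis_mm: float, short_axis_mm: float) -> float:
    """Average nodule diameter: arithmetic mean of the long and short axes."""
    if short_axis_mm < 0 or long_axis_mm < short_axis_mm:
        raise ValueError(
            f"axes must satisfy long >= short >= 0, got ({long_axis_mm}, {short_axis_mm})"
        )
    return (long_axis_mm + short_axis_mm) / 2.0


def compute_vdt(
    prior_volume_mm3: float, current_volume_mm3: float, delta_days: float
) -> VdtDays:
    """Volume doubling time in days under exponential growth.

    VDT = delta_days * ln(2) / ln(current / prior).  Returns the
    :data:`NOT_GROWING` sentinel when the volume did not strictly increase.
    """
    if prior_volume_mm3 <= 0:
        raise ValueError(f"prior volume must be positive, got {prior_volume_mm3}")
    if delta_days <= 0:
        raise ValueError(f"delta_days must be positive, got {delta_days}")
    if current_volume_mm3 <= prior_volume_mm3:
        return NOT_GROWING
    return delta_days * math.log(2.0) / math.log(current_volume_mm3 / prior_volume_mm3)


def observation_volume(obs: NoduleObservation) -> Optional[float]:
    """Best available volume for an observation: measured, else derived from diameter."""
    if obs.volume_mm3 is not None:
        return obs.volume_mm3
    if obs.avg_diameter_mm is not None:
        return sphere_volume(obs.avg_diameter_mm)
    return None


def assess_growth(
    prior: Optional[NoduleObservation],
    current: NoduleObservation,
    delta_days: float,
    cfg: Optional[GrowthConfig] = None,
) -> GrowthAssessment:
    """Classify the change of one nodule between two scans.

    ``prior is None`` means the nodule was first seen on the current scan
    (NEW).  Volumes are taken as measured when present, otherwise derived
    from the average diameter assuming a sphere.  GROWING means a relative
    volume increase of at least ``cfg.min_relative_volume_increase``; any
    smaller strict increase is SLOWLY_GROWING (for non-solid nodules this
    also covers indolent growth with VDT above ``cfg.slow_growth_vdt_days``).
    """
    cfg = cfg or GrowthConfig()
    if current.is_resolved:
        prior_vol = observation_volume(prior) if prior is not None else None
        return GrowthAssessment(
            prior_volume_mm3=prior_vol,
            current_volume_mm3=None,
            delta_days=delta_days,
            vdt_days=None,
            growth_class=GrowthClass.RESOLVED,
        )
    cur_vol = observation_volume(current)
    if prior is None:
        return GrowthAssessment(
            prior_volume_mm3=None,
            current_volume_mm3=cur_vol,
            delta_days=None,
            vdt_days=None,
            growth_class=GrowthClass.NEW,
        )
    if prior.nodule_id != current.nodule_id:
        raise ValueError(
            f"growth assessed across different nodules: {prior.nodule_id!r} vs "
            f"{current.nodule_id!r}"
        )
    prior_vol = observation_volume(prior)
    if prior_vol is None or cur_vol is None:
        raise UnsizedNoduleError(
            f"nodule {current.nodule_id!r}: no usable size on both scans"
        )
    if delta_days <= 0:
        raise ValueError(f"delta_days must be positive, got {delta_days}")
    vdt = compute_vdt(prior_vol, cur_vol, delta_days)
    rel_increase = (cur_vol - prior_vol) / prior_vol
    if cur_vol > prior_vol and rel_increase >= cfg.min_relative_volume_increase:
        growth_class = GrowthClass.GROWING
    elif cur_vol > prior_vol:
        growth_class = GrowthClass.SLOWLY_GROWING
    elif cur_vol < prior_vol:
        growth_class = GrowthClass.SHRINKING
    else:
        growth_class = GrowthClass.STABLE
    return GrowthAssessment(
        prior_volume_mm3=prior_vol,
        current_volume_mm3=cur_vol,
        delta_days=delta_days,
        vdt_days=vdt,
        growth_class=growth_class,
    )
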
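"""Scanner quality control and radiation-dose tracking.

Scanners must meet the program's minimum technical requirements (peak
kilovoltage 120-140 kVp, tube current 20-60 mAs, collimation <= 1 mm,
rotation time <= 0.5 s, CTDIvol <= 3.0 mGy, average effective dose
<= 1.5 mSv, >= 128 detector slices, slice thickness <= 1 mm).  Every scan's
effective dose is recorded and a cumulative dose is maintained per
participant.

All bounds are closed, as printed in the requirements table; the per-scan
dose limit is applied as <= 1.5 mSv (the table's "=<" governs over the
prose's "less than"), and each QC report notes this convention.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "ScannerProfile",
    "QCLimits",
    "DoseRecord",
    "ParameterVerdict",
    "ScannerQCReport",
    "DoseSummary",
    "qc_check_scanner",
    "qc_check_scan_dose",
    "cumulative_dose",
    "dose_summary",
]

_BOUNDARY_NOTE = (
    "All limits are closed bounds; the 1.5 mSv per-scan dose limit is "
    "applied inclusively (requirements-table convention)."
)


class ScannerProfile(BaseModel):
    """Technical parameters of one LDCT unit."""

    peak_kilovoltage_kVp: float = Field(gt=0)
    tube_current_mAs: float = Field(gt=0)
    collimation_mm: float = Field(gt=0)
    rotation_time_s: float = Field(gt=0)
    ctdi_vol_mGy: float = Field(gt=0)
    avg_effective_dose_mSv: float = Field(gt=0)
    detector_slices: int = Field(gt=0)
    slice_thickness_mm: float = Field(gt=0)


class QCLimits(BaseModel):
    """Minimum technical requirements; defaults as printed."""

    kVp_min: float = 120.0
    kVp_max: float = 140.0
    mAs_min: float = 20.0
    mAs_max: float = 60.0
    max_collimation_mm: float = 1.0
    max_rotation_time_s: float = 0.5
    max_ctdi_vol_mGy: float = 3.0
    max_effective_dose_mSv: float = 1.5
    min_detector_slices: int = 128
    max_slice_thickness_mm: float = 1.0


class DoseRecord(BaseModel):
    participant_id: str
    scan_id: str
    scan_date: date
    effective_dose_mSv: float = Field(gt=0)


class ParameterVerdict(BaseModel):
    value: float
    requirement: str
    passed: bool


class ScannerQCReport(BaseModel):
    parameters: dict[str, ParameterVerdict]
    overall_pass: bool
    note: str = _BOUNDARY_NOTE


class DoseSummary(BaseModel):
    n_scans: int
    mean_mSv: float
    max_mSv: float
    cumulative_by_participant: dict[str, float]


def qc_check_scanner(
    profile: ScannerProfile, limits: Optional[QCLimits] = None
) -> ScannerQCReport:
    """Check every scanner parameter against the program limits.

    One verdict per parameter; the scanner passes overall only when every
    parameter passes.
    """
    lm = limits or QCLimits()
    checks = {
        "peak_kilovoltage_kVp": (
            profile.peak_kilovoltage_kVp,
            f"{lm.kVp_min:g}-{lm.kVp_max:g} kVp",
            lm.kVp_min <= profile.peak_kilovoltage_kVp <= lm.kVp_max,
        ),
        "tube_current_mAs": (
            profile.tube_current_mAs,
            f"{lm.mAs_min:g}-{lm.mAs_max:g} mAs",
            lm.mAs_min <= profile.tube_current_mAs <= lm.mAs_max,
        ),
        "collimation_mm": (
            profile.collimation_mm,
            f"<= {lm.max_collimation_mm:g} mm",
            profile.collimation_mm <= lm.max_collimation_mm,
        ),
        "rotation_time_s": (
            profile.rotation_time_s,
            f"<= {lm.max_rotation_time_s:g} s",
            profile.rotation_time_s <= lm.max_rotation_time_s,
        ),
        "ctdi_vol_mGy": (
            profile.ctdi_vol_mGy,
            f"<= {lm.max_ctdi_vol_mGy:g} mGy",
            profile.ctdi_vol_mGy <= lm.max_ctdi_vol_mGy,
        ),
        "avg_effective_dose_mSv": (
            profile.avg_effective_dose_mSv,
            f"<= {lm.max_effective_dose_mSv:g} mSv",
            profile.avg_effective_dose_mSv <= lm.max_effective_dose_mSv,
        ),
        "detector_slices": (
            float(profile.detector_slices),
            f">= {lm.min_detector_slices} slices",
            profile.detector_slices >= lm.min_detector_slices,
        ),
        "slice_thickness_mm": (
            profile.slice_thickness_mm,
            f"<= {lm.max_slice_thickness_mm:g} mm",
            profile.slice_thickness_mm <= lm.max_slice_thickness_mm,
        ),
    }
    verdicts = {
        name: ParameterVerdict(value=value, requirement=req, passed=ok)
        for name, (value, req, ok) in checks.items()
    }
    return ScannerQCReport(
        parameters=verdicts, overall_pass=all(v.passed for v in verdicts.values())
    )


def qc_check_scan_dose(
    effective_dose_mSv: float, limits: Optional[QCLimits] = None
) -> bool:
    """Does one scan's effective dose meet the per-scan limit (inclusive)?"""
    if effective_dose_mSv <= 0:
        raise ValueError(f"effective dose must be positive, got {effective_dose_mSv}")
    lm = limits or QCLimits()
    return effective_dose_mSv <= lm.max_effective_dose_mSv


def cumulative_dose(records: Iterable[DoseRecord], participant_id: str) -> float:
    """Total effective dose (mSv) accrued by one participant; 0 if none."""
    return sum(
        r.effective_dose_mSv for r in records if r.participant_id == participant_id
    )


def dose_summary(records: Iterable[DoseRecord]) -> DoseSummary:
    """Mean and maximum per-scan dose plus per-participant cumulative doses."""
    recs = list(records)
    if not recs:
        raise ValueError("dose_summary requires at least one record")
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in recs],
            "dose": [r.effective_dose_mSv for r in recs],
        }
    )
    return DoseSummary(
        n_scans=len(recs),
        mean_mSv=float(df["dose"].mean()),
        max_mSv=float(df["dose"].max()),
        cumulative_by_participant=df.groupby("participant_id")["dose"].sum().to_dict(),
    )
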
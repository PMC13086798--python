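"""Readers and writers for the interchange formats, plus the structured report.

Conventions: CSV for batch data, JSON for single-record interchange, YAML
for configuration; UTF-8 everywhere; ISO-8601 dates; in CSV an empty string
means a missing value, never zero.

The nodule table may optionally carry ``prior_volume_mm3`` and
``delta_days`` columns; when present they are used to build growth
assessments so repeat and follow-up scans can be classified straight from
one file.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .eligibility import EligibilityCriteria, ExclusionFlag, Participant, SmokingStatus
from .engine import ScanClassification
from .nodule import (
    GrowthAssessment,
    GrowthConfig,
    NoduleObservation,
    NoduleType,
    ProtocolThresholds,
    assess_growth,
)
from .qc import DoseRecord, QCLimits, ScannerProfile

__all__ = [
    "ScanRecord",
    "TableFormatError",
    "read_nodule_table",
    "write_nodule_table",
    "read_roster",
    "write_roster",
    "read_scanner_profile",
    "write_scanner_profile",
    "read_dose_records",
    "load_config",
    "classification_to_dict",
    "write_classifications_csv",
    "Grade",
    "AncillaryFindings",
    "StructuredReport",
    "write_report",
    "read_report",
]

logger = logging.getLogger("lungscreen")

NODULE_COLUMNS = [
    "participant_id",
    "scan_id",
    "nodule_id",
    "type",
    "avg_diameter_mm",
    "volume_mm3",
    "solid_comp_diameter_mm",
    "solid_comp_volume_mm3",
    "is_new",
    "is_resolved",
    "location",
]
_OPTIONAL_GROWTH_COLUMNS = ["prior_volume_mm3", "delta_days"]


class TableFormatError(ValueError):
    """A malformed row or header in an interchange table."""


@dataclass
class ScanRecord:
    """All observations of one scan, with any growth assessments derived
    from the optional prior-volume columns."""

    participant_id: str
    scan_id: str
    observations: list[NoduleObservation] = field(default_factory=list)
    growth: dict[str, GrowthAssessment] = field(default_factory=dict)


def _parse_float(value: str, row: int, column: str) -> Optional[float]:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise TableFormatError(
            f"row {row}: column {column!r}: not a number: {value!r}"
        ) from None


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("", "false", "0", "no"):
        return False
    if v in ("true", "1", "yes"):
        return True
    raise TableFormatError(f"row {row}: column {column!r}: not a boolean: {value!r}")


def read_nodule_table(
    path: Union[str, Path], format: str = "csv", growth_cfg: Optional[GrowthConfig] = None
) -> list[ScanRecord]:
    """Read a nodule observation table and group rows by scan.

    Every row must parse; the first malformed row is reported with its row
    number and offending column.  A duplicate (scan_id, nodule_id) pair is a
    hard error.
    """
    path = Path(path)
    if format == "json":
        return _read_nodule_json(path, growth_cfg)
    if format != "csv":
        raise ValueError(f"unknown nodule table format: {format!r}")
    records: dict[tuple[str, str], ScanRecord] = {}
    seen: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file, header row is mandatory")
        missing = [c for c in NODULE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing required columns: {missing}")
        has_growth = all(c in reader.fieldnames for c in _OPTIONAL_GROWTH_COLUMNS)
        for rownum, row in enumerate(reader, start=2):
            key = (row["scan_id"], row["nodule_id"])
            if key in seen:
                raise TableFormatError(
                    f"row {rownum}: duplicate (scan_id, nodule_id) = {key}"
                )
            seen.add(key)
            type_raw = row["type"].strip()
            try:
                ntype = NoduleType(type_raw)
            except ValueError:
                raise TableFormatError(
                    f"row {rownum}: column 'type': unknown nodule type {type_raw!r}"
                ) from None
            try:
                obs = NoduleObservation(
                    nodule_id=row["nodule_id"],
                    nodule_type=ntype,
                    avg_diameter_mm=_parse_float(row["avg_diameter_mm"], rownum, "avg_diameter_mm"),
                    volume_mm3=_parse_float(row["volume_mm3"], rownum, "volume_mm3"),
                    solid_comp_diameter_mm=_parse_float(
                        row["solid_comp_diameter_mm"], rownum, "solid_comp_diameter_mm"
                    ),
                    solid_comp_volume_mm3=_parse_float(
                        row["solid_comp_volume_mm3"], rownum, "solid_comp_volume_mm3"
                    ),
                    is_new=_parse_bool(row["is_new"], rownum, "is_new"),
                    is_resolved=_parse_bool(row["is_resolved"], rownum, "is_resolved"),
                    location=row.get("location", ""),
                )
            except ValueError as exc:
                raise TableFormatError(f"row {rownum}: {exc}") from None
            scan_key = (row["participant_id"], row["scan_id"])
            record = records.setdefault(
                scan_key, ScanRecord(participant_id=scan_key[0], scan_id=scan_key[1])
            )
            record.observations.append(obs)
            if has_growth and not obs.is_new:
                prior_vol = _parse_float(row["prior_volume_mm3"], rownum, "prior_volume_mm3")
                delta = _parse_float(row["delta_days"], rownum, "delta_days")
                if prior_vol is not None and delta is not None:
                    prior = NoduleObservation(
                        nodule_id=obs.nodule_id,
                        nodule_type=obs.nodule_type,
                        volume_mm3=prior_vol,
                    )
                    record.growth[obs.nodule_id] = assess_growth(
                        prior, obs, delta, growth_cfg
                    )
    return list(records.values())


def _read_nodule_json(path: Path, growth_cfg: Optional[GrowthConfig]) -> list[ScanRecord]:
    data = json.loads(path.read_text(encoding="utf-8"))
    records: list[ScanRecord] = []
    for scan in data:
        record = ScanRecord(
            participant_id=scan["participant_id"], scan_id=scan["scan_id"]
        )
        for nod in scan["nodules"]:
            growth_fields = {
                k: nod.pop(k, None) for k in _OPTIONAL_GROWTH_COLUMNS
            }
            obs = NoduleObservation(**nod)
            record.observations.append(obs)
            if (
                not obs.is_new
                and growth_fields["prior_volume_mm3"] is not None
                and growth_fields["delta_days"] is not None
            ):
                prior = NoduleObservation(
                    nodule_id=obs.nodule_id,
                    nodule_type=obs.nodule_type,
                    volume_mm3=growth_fields["prior_volume_mm3"],
                )
                record.growth[obs.nodule_id] = assess_growth(
                    prior, obs, growth_fields["delta_days"], growth_cfg
                )
        records.append(record)
    return records


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_nodule_table(records: Sequence[ScanRecord], path: Union[str, Path]) -> None:
    """Write scan records back to the canonical CSV layout."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(NODULE_COLUMNS)
        for record in records:
            for obs in record.observations:
                writer.writerow(
                    [
                        record.participant_id,
                        record.scan_id,
                        obs.nodule_id,
                        obs.nodule_type.value,
                        _fmt(obs.avg_diameter_mm),
                        _fmt(obs.volume_mm3),
                        _fmt(obs.solid_comp_diameter_mm),
                        _fmt(obs.solid_comp_volume_mm3),
                        "true" if obs.is_new else "false",
                        "true" if obs.is_resolved else "false",
                        obs.location,
                    ]
                )


ROSTER_COLUMNS = [
    "participant_id",
    "age_years",
    "smoking_status",
    "pack_years",
    "years_since_quit",
    "flags",
]


def read_roster(path: Union[str, Path]) -> list[Participant]:
    """Read a participant roster CSV; flags are semicolon-separated codes."""
    participants: list[Participant] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file, header row is mandatory")
        missing = [c for c in ROSTER_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing required columns: {missing}")
        for rownum, row in enumerate(reader, start=2):
            flags_raw = [f for f in row["flags"].split(";") if f.strip()]
            try:
                flags = {ExclusionFlag(f.strip()) for f in flags_raw}
                participants.append(
                    Participant(
                        participant_id=row["participant_id"],
                        age_years=int(row["age_years"]),
                        smoking_status=SmokingStatus(row["smoking_status"].strip()),
                        pack_years=float(row["pack_years"]),
                        years_since_quit=_parse_float(
                            row["years_since_quit"], rownum, "years_since_quit"
                        ),
                        exclusion_flags=flags,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise TableFormatError(f"row {rownum}: {exc}") from None
    return participants


def write_roster(participants: Sequence[Participant], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for p in participants:
            writer.writerow(
                [
                    p.participant_id,
                    p.age_years,
                    p.smoking_status.value,
                    repr(p.pack_years),
                    _fmt(p.years_since_quit),
                    ";".join(sorted(f.value for f in p.exclusion_flags)),
                ]
            )


def read_scanner_profile(path: Union[str, Path]) -> ScannerProfile:
    return ScannerProfile(**json.loads(Path(path).read_text(encoding="utf-8")))


def write_scanner_profile(profile: ScannerProfile, path: Union[str, Path]) -> None:
    Path(path).write_text(profile.model_dump_json(indent=2), encoding="utf-8")


def read_dose_records(path: Union[str, Path]) -> list[DoseRecord]:
    records: list[DoseRecord] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            try:
                records.append(DoseRecord(**row))
            except ValueError as exc:
                raise TableFormatError(f"row {rownum}: {exc}") from None
    return records


@dataclass
class ProgramConfig:
    """The protocol, growth, QC and eligibility settings in one place.

    The defaults reproduce the program's printed thresholds exactly.
    """

    thresholds: ProtocolThresholds = field(default_factory=ProtocolThresholds)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    qc_limits: QCLimits = field(default_factory=QCLimits)
    eligibility: EligibilityCriteria = field(default_factory=EligibilityCriteria)


def load_config(path: Union[str, Path]) -> ProgramConfig:
    """Load threshold/criteria overrides from a single YAML file.

    Any omitted section keeps its printed default.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return ProgramConfig(
        thresholds=ProtocolThresholds(**raw.get("thresholds", {})),
        growth=GrowthConfig(**raw.get("growth", {})),
        qc_limits=QCLimits(**raw.get("qc_limits", {})),
        eligibility=EligibilityCriteria(**raw.get("eligibility", {})),
    )


def classification_to_dict(
    participant_id: str, scan_id: str, classification: ScanClassification
) -> dict:
    """Flatten one scan classification to the interchange JSON layout."""
    return {
        "participant_id": participant_id,
        "scan_id": scan_id,
        "category": classification.category.value,
        "action": classification.action.value,
        "interval_months": classification.interval_months,
        "consider_antibiotics": classification.consider_antibiotics,
        "rule_code": classification.rule_code,
        "driving_nodule_id": classification.driving_nodule_id,
        "trace": [list(t) for t in classification.trace],
    }


def write_classifications_csv(
    rows: Sequence[tuple[str, str, ScanClassification]], path: Union[str, Path]
) -> None:
    """Batch CSV variant: one row per classified scan."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "participant_id",
                "scan_id",
                "category",
                "action",
                "interval_months",
                "consider_antibiotics",
                "rule_code",
                "driving_nodule_id",
            ]
        )
        for pid, sid, c in rows:
            writer.writerow(
                [
                    pid,
                    sid,
                    c.category.value,
                    c.action.value,
                    "" if c.interval_months is None else c.interval_months,
                    "true" if c.consider_antibiotics else "false",
                    c.rule_code,
                    c.driving_nodule_id or "",
                ]
            )


def log_classification(
    participant_id: str, scan_id: str, classification: ScanClassification
) -> None:
    """One structured audit line per classified scan."""
    logger.info(
        "scan classified participant=%s scan=%s category=%s rule=%s interval=%s",
        participant_id,
        scan_id,
        classification.category.value,
        classification.rule_code,
        classification.interval_months,
    )


# --------------------------------------------------------------------------
# Structured radiology report
# --------------------------------------------------------------------------

class Grade(str, enum.Enum):
    """Four-stage visual scale for ancillary findings."""

    NONE = "NONE"
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


class AncillaryFindings(BaseModel):
    """Non-nodule findings reported on every screening LDCT: emphysema and
    coronary-artery-calcification grades plus aortic and pulmonary-artery
    diameters."""

    emphysema_grade: Grade = Grade.NONE
    cac_grade: Grade = Grade.NONE
    aorta_diameter_mm: Optional[float] = Field(default=None, gt=0)
    pulmonary_artery_diameter_mm: Optional[float] = Field(default=None, gt=0)


class NoduleFinding(BaseModel):
    observation: NoduleObservation
    rule_codes: list[str] = Field(default_factory=list)


class StructuredReport(BaseModel):
    """The machine-readable radiology report for one screening scan.

    Per-scan effective dose and the participant's cumulative dose are
    mandatory fields.
    """

    participant_id: str
    scan_id: str
    effective_dose_mSv: float = Field(gt=0)
    cumulative_dose_mSv: float = Field(gt=0)
    findings: list[NoduleFinding] = Field(default_factory=list)
    classification: ScanClassification
    ancillary: AncillaryFindings = Field(default_factory=AncillaryFindings)
    significant_ancillary_flag: bool = False

    @model_validator(mode="after")
    def _check_dose(self) -> "StructuredReport":
        if self.cumulative_dose_mSv + 1e-12 < self.effective_dose_mSv:
            raise ValueError("cumulative dose cannot be below the per-scan dose")
        return self


def write_report(report: StructuredReport, path: Union[str, Path]) -> None:
    """Serialise a validated report to JSON with a stable field order."""
    Path(path).write_text(report.model_dump_json(indent=2), encoding="utf-8")


def read_report(path: Union[str, Path]) -> StructuredReport:
    return StructuredReport(**json.loads(Path(path).read_text(encoding="utf-8")))
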
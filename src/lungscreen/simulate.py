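"""Synthetic screening cohorts and multi-round program microsimulation.

The generator creates eligible participants, a subset of whom carry
pulmonary nodules with a hidden natural history: a true type, a true
baseline volume, and a true volume doubling time (VDT) — finite for growing
nodules, the :data:`~lungscreen.nodule.NOT_GROWING` sentinel otherwise.
Nodule growth is exponential in volume, the standard kinetic model
underlying the VDT.  The protocol engine never sees the truth: it sees
volumes corrupted by multiplicative log-normal measurement noise with a
configurable coefficient of variation, with diameters always derived from
the noisy volume.

``run_program`` then walks every participant through the scheduled rounds
(baseline, annual/biennial repeats, interim follow-ups), classifying each
scan with the management rules; a referral ends screening for that
participant.  Everything is deterministic under a fixed seed.

All default distribution parameters are fabricated for testability; they
are not estimates of any real screening cohort.
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .eligibility import Participant, SmokingStatus
from .engine import (
    Action,
    Category,
    ScanClassification,
    classify_scan,
    next_round_type,
)
from .nodule import (
    NOT_GROWING,
    GrowthAssessment,
    GrowthConfig,
    NoduleObservation,
    NoduleType,
    ProtocolThresholds,
    RoundType,
    ScanContext,
    VdtDays,
    assess_growth,
    equivalent_diameter,
)

__all__ = [
    "SimulationConfig",
    "NoduleNaturalHistory",
    "SimulatedParticipant",
    "ScanEvent",
    "RoundStats",
    "ProgramResults",
    "grow_nodule",
    "generate_cohort",
    "observe_nodule",
    "run_program",
    "summarize_results",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
DAYS_PER_YEAR = 365.25


class SimulationConfig(BaseModel):
    """All knobs of the cohort generator and program loop."""

    n_participants: int = Field(default=1000, gt=0)
    seed: int = 0
    nodule_prevalence: float = Field(default=0.25, ge=0, le=1)
    nodules_per_affected_mean: float = Field(default=1.3, ge=1)
    type_mix: dict[NoduleType, float] = Field(
        default_factory=lambda: {
            NoduleType.SOLID: 0.60,
            NoduleType.PART_SOLID: 0.08,
            NoduleType.NON_SOLID: 0.12,
            NoduleType.ENDOBRONCHIAL: 0.02,
            NoduleType.CALCIFIED: 0.18,
        }
    )
    baseline_diameter_median_mm: float = Field(default=4.5, gt=0)
    baseline_diameter_sigma: float = Field(default=0.55, gt=0)
    malignant_fraction: float = Field(default=0.01, ge=0, le=1)
    malignant_vdt_median_days: float = Field(default=250.0, gt=0)
    malignant_vdt_sigma: float = Field(default=0.4, gt=0)
    benign_slow_growth_prob: float = Field(default=0.10, ge=0, le=1)
    benign_vdt_median_days: float = Field(default=1200.0, gt=0)
    benign_vdt_sigma: float = Field(default=0.3, gt=0)
    benign_vdt_floor_days: float = Field(default=800.0, gt=0)
    volume_measurement_cv: float = Field(default=0.10, ge=0)
    new_nodule_rate_per_year: float = Field(default=0.02, ge=0)
    dose_per_scan_mSv: float = Field(default=0.9, gt=0)
    horizon_years: int = Field(default=5, ge=1)

    @model_validator(mode="after")
    def _check_mix(self) -> "SimulationConfig":
        total = sum(self.type_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"type_mix probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.type_mix.values()):
            raise ValueError("type_mix probabilities must be non-negative")
        return self


class NoduleNaturalHistory(BaseModel):
    """Hidden truth for one nodule; never shown to the protocol engine."""

    nodule_id: str
    true_type: NoduleType
    baseline_volume_mm3: float = Field(gt=0)
    vdt_days: VdtDays
    malignant: bool
    appearance_day: float = Field(default=0.0, ge=0)
    solid_comp_fraction: Optional[float] = Field(default=None, gt=0, le=1)


class SimulatedParticipant(BaseModel):
    participant: Participant
    nodules: list[NoduleNaturalHistory] = Field(default_factory=list)


class ScanEvent(BaseModel):
    """One row of the per-scan event log."""

    participant_id: str
    scan_id: str
    scan_index: int
    round_type: RoundType
    day: float
    category: Category
    rule_code: str
    interval_months: Optional[int]
    dose_mSv: float


class RoundStats(BaseModel):
    round_index: int
    n_scans: int
    n_negative: int
    n_semi_positive: int
    n_positive: int
    positivity: float

    @model_validator(mode="after")
    def _check(self) -> "RoundStats":
        if self.n_negative + self.n_semi_positive + self.n_positive != self.n_scans:
            raise ValueError("category counts must sum to the number of scans")
        return self


class ProgramResults(BaseModel):
    n_participants: int
    rounds: list[RoundStats]
    rounds_simulated: int
    referral_count: int
    detected_malignant_count: int
    interval_histogram: dict[int, int]
    cumulative_dose_mSv: dict[str, float]
    events: list[ScanEvent]


def grow_nodule(volume_mm3: float, vdt_days: VdtDays, delta_days: float) -> float:
    """Volume after ``delta_days`` of exponential growth: v * 2**(dt / VDT).

    Non-growing nodules (the sentinel) are returned unchanged.
    """
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    if delta_days < 0:
        raise ValueError(f"delta_days must be non-negative, got {delta_days}")
    if vdt_days == NOT_GROWING:
        return volume_mm3
    return volume_mm3 * 2.0 ** (delta_days / float(vdt_days))


def _sample_nodule(
    cfg: SimulationConfig, rng: np.random.Generator, nodule_id: str, appearance_day: float
) -> NoduleNaturalHistory:
    types = list(cfg.type_mix.keys())
    probs = np.array([cfg.type_mix[t] for t in types])
    ntype = types[int(rng.choice(len(types), p=probs / probs.sum()))]
    diameter = cfg.baseline_diameter_median_mm * math.exp(
        cfg.baseline_diameter_sigma * rng.standard_normal()
    )
    volume = math.pi * diameter**3 / 6.0
    malignant = ntype is not NoduleType.CALCIFIED and rng.random() < cfg.malignant_fraction
    vdt: VdtDays
    if malignant:
        vdt = cfg.malignant_vdt_median_days * math.exp(
            cfg.malignant_vdt_sigma * rng.standard_normal()
        )
    elif ntype is not NoduleType.CALCIFIED and rng.random() < cfg.benign_slow_growth_prob:
        # Indolent benign growth: VDT bounded away from the suspicious bands.
        vdt = cfg.benign_vdt_floor_days
        while True:
            draw = cfg.benign_vdt_median_days * math.exp(
                cfg.benign_vdt_sigma * rng.standard_normal()
            )
            if draw > cfg.benign_vdt_floor_days:
                vdt = draw
                break
    else:
        vdt = NOT_GROWING
    solid_frac = None
    if ntype is NoduleType.PART_SOLID:
        solid_frac = float(rng.uniform(0.1, 0.6))
    return NoduleNaturalHistory(
        nodule_id=nodule_id,
        true_type=ntype,
        baseline_volume_mm3=volume,
        vdt_days=vdt,
        malignant=malignant,
        appearance_day=appearance_day,
        solid_comp_fraction=solid_frac,
    )


def generate_cohort(cfg: SimulationConfig) -> list[SimulatedParticipant]:
    """Sample a cohort of eligible participants with hidden nodule histories.

    Deterministic under a fixed ``cfg.seed``.  Every generated participant
    satisfies the program's inclusion criteria; nodule carriage follows
    ``cfg.nodule_prevalence``, and incident nodules appear at a constant
    per-year hazard over the simulation horizon.
    """
    rng = np.random.default_rng(cfg.seed)
    horizon_days = cfg.horizon_years * DAYS_PER_YEAR
    cohort: list[SimulatedParticipant] = []
    for i in range(cfg.n_participants):
        pid = f"P{i:06d}"
        age = int(rng.integers(50, 76))
        if rng.random() < 0.55:
            status, quit_years = SmokingStatus.CURRENT, None
        else:
            status, quit_years = SmokingStatus.FORMER, float(rng.uniform(0, 15))
        pack_years = 30.0 + float(rng.exponential(15.0))
        participant = Participant(
            participant_id=pid,
            age_years=age,
            smoking_status=status,
            pack_years=pack_years,
            years_since_quit=quit_years,
        )
        nodules: list[NoduleNaturalHistory] = []
        if rng.random() < cfg.nodule_prevalence:
            # Poisson-like count truncated at >= 1: 1 + Poisson(mean - 1).
            count = 1 + int(rng.poisson(cfg.nodules_per_affected_mean - 1.0))
            for k in range(count):
                nodules.append(_sample_nodule(cfg, rng, f"{pid}-N{k}", 0.0))
        n_incident = int(rng.poisson(cfg.new_nodule_rate_per_year * cfg.horizon_years))
        for k in range(n_incident):
            day = float(rng.uniform(1.0, horizon_days))
            nodules.append(
                _sample_nodule(cfg, rng, f"{pid}-X{k}", day)
            )
        cohort.append(SimulatedParticipant(participant=participant, nodules=nodules))
    return cohort


def observe_nodule(
    truth: NoduleNaturalHistory,
    true_volume_mm3: float,
    measurement_cv: float,
    rng: np.random.Generator,
    *,
    is_new: bool = False,
) -> NoduleObservation:
    """Turn a true nodule state into a noisy scan observation.

    The observed volume is the true volume times a log-normal factor whose
    coefficient of variation equals ``measurement_cv`` (median-unbiased, so
    cv = 0 reproduces the truth exactly); the diameter is always the
    equivalent sphere diameter of the noisy volume, never noised separately.
    """
    if true_volume_mm3 <= 0:
        raise ValueError(f"true volume must be positive, got {true_volume_mm3}")
    if measurement_cv > 0:
        sigma = math.sqrt(math.log(1.0 + measurement_cv**2))
        observed = true_volume_mm3 * math.exp(sigma * rng.standard_normal())
    else:
        observed = true_volume_mm3
    solid_d = solid_v = None
    if truth.true_type is NoduleType.PART_SOLID and truth.solid_comp_fraction is not None:
        solid_v = observed * truth.solid_comp_fraction
        solid_d = equivalent_diameter(solid_v)
    return NoduleObservation(
        nodule_id=truth.nodule_id,
        nodule_type=truth.true_type,
        avg_diameter_mm=equivalent_diameter(observed),
        volume_mm3=observed,
        solid_comp_diameter_mm=solid_d,
        solid_comp_volume_mm3=solid_v,
        is_new=is_new,
    )


def run_program(
    cohort: Sequence[SimulatedParticipant],
    cfg: SimulationConfig,
    thresholds: Optional[ProtocolThresholds] = None,
    growth_cfg: Optional[GrowthConfig] = None,
) -> ProgramResults:
    """Run the full multi-round screening protocol over a cohort.

    Event-driven loop per participant: scan at the scheduled day, grow every
    present nodule to that day, observe with noise, classify, then schedule
    the next round from the classification (a referral stops screening for
    that participant).  Observation noise uses a stream derived from
    ``cfg.seed`` so the whole run is seed-deterministic.
    """
    thresholds = thresholds or ProtocolThresholds()
    growth_cfg = growth_cfg or GrowthConfig()
    horizon_days = cfg.horizon_years * DAYS_PER_YEAR
    events: list[ScanEvent] = []
    referral_count = 0
    detected_malignant = 0
    cumulative: dict[str, float] = {}
    max_rounds = 0

    for person_idx, sim in enumerate(cohort):
        pid = sim.participant.participant_id
        # Independent per-participant noise stream: results do not depend on
        # how many scans earlier participants received.
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, person_idx))
        )
        day = 0.0
        round_type = RoundType.BASELINE
        scan_index = 0
        prev_obs: dict[str, NoduleObservation] = {}
        prev_day = 0.0
        cumulative[pid] = 0.0
        while day <= horizon_days + 1e-9:
            scan_index += 1
            present = [n for n in sim.nodules if n.appearance_day <= day]
            observations: list[NoduleObservation] = []
            growth: dict[str, GrowthAssessment] = {}
            for truth in present:
                true_vol = grow_nodule(
                    truth.baseline_volume_mm3, truth.vdt_days, day - truth.appearance_day
                )
                new = round_type is not RoundType.BASELINE and truth.nodule_id not in prev_obs
                obs = observe_nodule(
                    truth, true_vol, cfg.volume_measurement_cv, rng, is_new=new
                )
                observations.append(obs)
                if not new and round_type is not RoundType.BASELINE:
                    growth[truth.nodule_id] = assess_growth(
                        prev_obs[truth.nodule_id], obs, day - prev_day, growth_cfg
                    )
            context = ScanContext(
                round_type=round_type,
                days_since_prior=(day - prev_day) if round_type is not RoundType.BASELINE else None,
                effective_dose_mSv=cfg.dose_per_scan_mSv,
            )
            result = classify_scan(context, observations, growth, thresholds)
            cumulative[pid] += cfg.dose_per_scan_mSv
            events.append(
                ScanEvent(
                    participant_id=pid,
                    scan_id=f"{pid}-S{scan_index}",
                    scan_index=scan_index,
                    round_type=round_type,
                    day=day,
                    category=result.category,
                    rule_code=result.rule_code,
                    interval_months=result.interval_months,
                    dose_mSv=cfg.dose_per_scan_mSv,
                )
            )
            max_rounds = max(max_rounds, scan_index)
            if result.action is Action.REFER_NODULE_CLINIC:
                referral_count += 1
                if any(n.malignant for n in present):
                    detected_malignant += 1
                break
            nxt = next_round_type(result, context)
            assert nxt is not None and result.interval_months is not None
            prev_obs = {o.nodule_id: o for o in observations if not o.is_resolved}
            prev_day = day
            day += result.interval_months * DAYS_PER_MONTH
            round_type = nxt

    round_stats: list[RoundStats] = []
    for idx in range(1, max_rounds + 1):
        batch = [e for e in events if e.scan_index == idx]
        n_neg = sum(1 for e in batch if e.category is Category.NEGATIVE)
        n_semi = sum(1 for e in batch if e.category is Category.SEMI_POSITIVE)
        n_pos = sum(1 for e in batch if e.category is Category.POSITIVE)
        round_stats.append(
            RoundStats(
                round_index=idx,
                n_scans=len(batch),
                n_negative=n_neg,
                n_semi_positive=n_semi,
                n_positive=n_pos,
                positivity=n_pos / len(batch) if batch else 0.0,
            )
        )
    histogram: dict[int, int] = {}
    for e in events:
        if e.interval_months is not None:
            histogram[e.interval_months] = histogram.get(e.interval_months, 0) + 1
    return ProgramResults(
        n_participants=len(cohort),
        rounds=round_stats,
        rounds_simulated=max_rounds,
        referral_count=referral_count,
        detected_malignant_count=detected_malignant,
        interval_histogram=histogram,
        cumulative_dose_mSv=cumulative,
        events=events,
    )


def summarize_results(results: ProgramResults) -> tuple[str, dict]:
    """Human-readable per-round table plus a JSON-ready summary dict.

    Fractions are recomputed from the counts and checked for internal
    consistency.
    """
    lines = [
        f"{'round':>5} {'scans':>7} {'negative':>9} {'semi-pos':>9} "
        f"{'positive':>9} {'positivity':>11}"
    ]
    for r in results.rounds:
        total = r.n_negative + r.n_semi_positive + r.n_positive
        if total != r.n_scans:
            raise ValueError("inconsistent round counts")
        positivity = r.n_positive / r.n_scans if r.n_scans else 0.0
        lines.append(
            f"{r.round_index:>5} {r.n_scans:>7} {r.n_negative:>9} "
            f"{r.n_semi_positive:>9} {r.n_positive:>9} {positivity:>11.4f}"
        )
    lines.append(
        f"referrals: {results.referral_count}  "
        f"detected malignant: {results.detected_malignant_count}"
    )
    summary = {
        "n_participants": results.n_participants,
        "rounds_simulated": results.rounds_simulated,
        "referral_count": results.referral_count,
        "detected_malignant_count": results.detected_malignant_count,
        "interval_histogram": {str(k): v for k, v in sorted(results.interval_histogram.items())},
        "rounds": [
            {
                "round_index": r.round_index,
                "n_scans": r.n_scans,
                "n_negative": r.n_negative,
                "n_semi_positive": r.n_semi_positive,
                "n_positive": r.n_positive,
                "positivity": (r.n_positive / r.n_scans) if r.n_scans else 0.0,
            }
            for r in results.rounds
        ],
        "mean_cumulative_dose_mSv": (
            sum(results.cumulative_dose_mSv.values()) / len(results.cumulative_dose_mSv)
            if results.cumulative_dose_mSv
            else 0.0
        ),
    }
    # The dict must survive a JSON round-trip unchanged.
    assert json.loads(json.dumps(summary)) == summary
    return "\n".join(lines), summary
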
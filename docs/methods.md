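# Methods

## Rule engine

The management table is implemented as one pure function per screening-round
column (`classify_baseline`, `classify_repeat`, `classify_followup`) with a
dispatcher (`classify_scan`) and a scheduler (`next_round_type`). Every
numeric constant lives in `ProtocolThresholds` so the defaults reproduce the
printed table exactly while remaining overridable through one YAML file.

Conventions that the printed table leaves open, resolved here as package
design choices:

* **Boundaries.** "≥" thresholds are closed below and "<" open above, as
  printed. The VDT bands would overlap at exactly 600 days ("VDT ≥ 600" vs
  "VDT 400–600"); 600 d itself is assigned to the annual-return cell, so the
  semi-positive band is [400, 600). The follow-up largeness bound is
  strictly "larger than" 15 mm / 2000 mm³, again as printed — note this is
  15 mm, not the baseline column's 15.5 mm, and the two are independent
  constants.
* **Independent diameter/volume criteria.** The table pairs 6.5 mm with
  150 mm³ and 15.5 mm with 2000 mm³ although the exact sphere volumes are
  143.8 and 1949.8 mm³. The thresholds are therefore kept as two independent
  criteria and never recomputed from one another. When a nodule carries both
  a measured volume and a diameter and they disagree across a threshold, the
  volume governs (the program is volumetric by design) and an advisory
  `VOL.governs` entry is left in the trace.
* **Average diameter** is the arithmetic mean of the long and short axes,
  the I-ELCAP convention; the sizes in observations are assumed to already
  be average diameters.
* **"Growing".** The table names no growth criterion. The default is a
  relative volume increase ≥ 30 % between paired scans (`GrowthConfig`,
  configurable); any smaller strict increase is "slowly growing". With the
  threshold set to 0 every strict increase classifies as growing.
* **Multi-nodule scans.** The table describes single findings. Aggregation:
  scan category = maximum severity over nodules; among repeat
  recommendations the shortest interval wins; a referral dominates
  everything; calcified nodules never contribute. The driving nodule and
  every fired rule are reported in the trace.
* **Part-solid nodules** are judged by their solid component wherever the
  rules size a nodule, including the follow-up largeness bound; if no
  component measurement was recorded the overall size is used as a
  conservative fallback. At baseline a solid component ≥ 15.5 mm / 2000 mm³
  is positive by symmetry with the "< 15.5 mm" upper bound of the 3-month
  cell, although the printed positive cell names only solid nodules.
* **Emergent solid component.** The repeat-column referral for "non-solid
  nodule doubled in volume in 1 year (only if a solid component emerges)"
  is triggered by a nodule that now presents as part-solid with a measured
  doubling time ≤ 365 days. A non-solid nodule doubling within a year
  *without* a solid component is not positive under the printed rule; it
  stays in the 12-month non-solid cell with an advisory `RPT.c1.watch`
  trace entry.
* **Endobronchial nodules**: any at baseline → 1-month recall; new on a
  repeat → 1-month recall; persistent (present and not new on a later scan)
  → referral.
* **Nodules first seen on an interim follow-up** have no VDT pair, so the
  repeat-column new-nodule rules apply to them.
* **Antibiotics** ("consider antibiotics before the 1-month LDCT") is
  advisory metadata only; it never changes the category or interval.
* The table's bottom summary row disagrees with one cell body ("in 6 or 9
  months – at 12 months"); the cell text (12 months) governs.

Scheduling: 24-month negative results move the participant to biennial
screening; 12-month results keep the annual schedule; 1/3/6-month recalls
are interim follow-ups; a referral ends scheduled screening.

## Eligibility and QC

All eligibility bounds are closed (ages 50 and 75, exactly 30 pack-years and
exactly 15 years since quitting all qualify), matching the inclusive ranges
used by the large screening trials this program draws on. Exclusion criteria
are caller-supplied boolean flags — they encode a physician's judgment, not
a computation. Age is evaluated at assessment time.

Scanner QC treats every printed bound as closed. The per-scan dose limit is
applied inclusively (≤ 1.5 mSv); the requirement table also names this limit
for the scanner's *average* effective dose, so both a per-scan check
(`qc_check_scan_dose`) and a profile-level check (via `qc_check_scanner`)
are provided. Cumulative dose per participant is a plain sum of that
participant's scan doses.

## Microsimulator

Each simulated participant satisfies the inclusion criteria by construction
(age uniform on 50–75, ≥ 30 pack-years, current or recently-quit smoker).
Nodule natural history is deliberately minimal:

* Growth is **exponential in volume** — the kinetic model under the VDT —
  with a fixed per-nodule true VDT; there is no Gompertz or stochastic
  growth option in this version.
* Measurement error is **multiplicative log-normal on volume** with
  coefficient of variation `volume_measurement_cv` (default 0.10, a typical
  repeat-volumetry figure); diameters are always derived from the noisy
  volume via sphere volumetry, never noised independently. With cv = 0 the
  truth is reproduced exactly, which the tests exploit for parameter
  recovery.
* Defaults (all fabricated for testability, not estimates of any real
  cohort): baseline nodule prevalence 0.25; nodule count per affected
  participant 1 + Poisson(0.3) (mean 1.3, truncated ≥ 1); type mix
  60 % solid, 8 % part-solid, 12 % non-solid, 2 % endobronchial,
  18 % calcified; baseline diameter log-normal with median 4.5 mm and
  σ = 0.55; 1 % of non-calcified nodules malignant with VDT log-normal
  (median 250 d, σ = 0.4); benign nodules non-growing except a 10 % slow
  fraction with VDT > 800 d; incident nodules at 0.02 per participant-year;
  0.9 mSv per scan; 5-year horizon.
* The program loop is event-driven per participant: grow nodules to the
  scan day, observe with noise, classify, schedule the next round from the
  classification; a referral removes the participant. Each participant has
  an independent noise stream spawned from the seed, so results are
  byte-reproducible and insensitive to cohort ordering.

What the simulator does **not** model — and hence what passing tests do not
show about real data: nodule resolution (benign nodules never disappear, so
the "resolved" follow-up path is exercised only by unit tests), reader
variability beyond volumetry noise, attendance/drop-out, inter-scan nodule
matching errors, death or competing risks, and diagnostic work-up after
referral. Program-level outputs (positivity, referral counts) are
self-consistency checks, not predictions for any real screening program,
and are deliberately not calibrated to published cohort outcomes.

## Numerical and testing notes

* VDT is undefined for non-growing nodules; a portable string sentinel
  (`NOT_GROWING`) is used rather than infinity so JSON/CSV round-trips are
  lossless.
* Sphere volumetry round-trips diameter↔volume to 1e-9 mm over the 0–50 mm
  range; VDT recovery from simulated growth is exact to 1e-9 relative.
* Months are converted to days with 30.4375 d/month (365.25/12) in the
  simulator's schedule.
* The rule engine is verified cell-by-cell against an independently written
  flat decision-table oracle over a grid of ~270,000 single-nodule
  scenarios (all types × 0.1–30 mm in 0.1 mm steps × diameter-only and
  volume-bearing variants × growth classes × VDT 100–900 d in 10 d steps)
  plus randomized multi-nodule scans, and by a 10,000-pair randomized
  monotonicity suite (larger size or shorter VDT never lowers severity nor
  lengthens the recall). Simulator determinism and self-consistency are
  checked at 10,000 participants over a 5-year horizon, sizes at which the
  whole suite runs in well under a minute.
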
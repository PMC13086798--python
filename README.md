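# lungscreen

A deterministic, auditable implementation of a national low-dose-CT (LDCT)
lung-cancer-screening protocol: the nodule-management decision rules of a
volumetric, modified I-ELCAP scheme, together with eligibility screening,
scanner and radiation-dose quality control, and a synthetic-cohort
microsimulator that runs the full multi-round program.

It is written for screening-program engineers, health-services researchers
and guideline implementers who need the management rules as *testable code*
rather than a table in a document: every classification carries the rule
code of the table cell that produced it and a trace of every rule that
fired, so any recommendation can be audited back to the protocol.

## The protocol in brief

Nodules are managed by attenuation class (solid, part-solid, non-solid
/ ground-glass, endobronchial, calcified), by size, and — on follow-up — by
growth rate. Sizes are expressed both as the average diameter
*d* = (long + short)/2 in mm and as a volume in mm³; the diameter and
volume thresholds are **independent** printed criteria (6.5 mm ↔ 150 mm³,
15.5 mm ↔ 2000 mm³, 3.0 mm ↔ 20 mm³), and when a measured volume is present
it governs. Growth rate is summarised by the volume doubling time under
exponential growth,

    VDT = Δt · ln 2 / ln(V₂ / V₁)   [days],

with sphere volumetry V = π d³ / 6 linking diameters to volumes.

Each scan is classified **NEGATIVE**, **SEMI-POSITIVE (indeterminate)** or
**POSITIVE**, with an action: repeat LDCT in 1, 3, 6, 12 or 24 months, or
referral to the screening pulmonologist / nodule clinic. At baseline,
severity is driven by the largest solid nodule (or solid component); on
annual/biennial repeats only *new or growing* nodules can raise the result;
on interim follow-ups the VDT bands decide (< 400 d → positive; 400–600 d →
6-month recall, or referral if the nodule is larger than 15 mm / 2000 mm³;
≥ 600 d → back to the annual schedule). Participants whose results are
negative move to biennial screening. Eligibility: age 50–75, ≥ 30
pack-years, current smoker or quit within 15 years, none of six exclusion
criteria. Scanners must meet minimum technical requirements (e.g. CTDIvol
≤ 3.0 mGy, effective dose ≤ 1.5 mSv per scan, ≥ 128 detector slices).

## Worked example

`nodules.csv` describes one baseline scan with a 10 mm solid nodule and an
incidental calcified nodule:

```csv
participant_id,scan_id,nodule_id,type,avg_diameter_mm,volume_mm3,solid_comp_diameter_mm,solid_comp_volume_mm3,is_new,is_resolved,location
HR0001,SCAN1,n1,SOLID,10,,,,false,false,right upper lobe
HR0001,SCAN1,n2,CALCIFIED,4,,,,false,false,left lower lobe
```

```sh
$ lungscreen classify --nodules nodules.csv --context baseline
[
  {
    "participant_id": "HR0001",
    "scan_id": "SCAN1",
    "category": "SEMI_POSITIVE",
    "action": "REPEAT_LDCT",
    "interval_months": 3,
    "consider_antibiotics": false,
    "rule_code": "BL.b3",
    "driving_nodule_id": "n1",
    "trace": [["n1", "BL.b3"]]
  }
]
```

The 10 mm solid nodule falls in the 6.5–15.5 mm baseline band (rule cell
`BL.b3`), so the scan is semi-positive with a 3-month recall; the calcified
nodule is benign and contributes nothing. The same logic is available as a
library (`classify_baseline`, `classify_repeat`, `classify_followup`,
`classify_scan`), and `lungscreen eligibility`, `lungscreen qc` and
`lungscreen simulate` cover the other components. A 1000-participant
microsimulation (`lungscreen simulate --seed 1`) prints a per-round table —

```
round   scans  negative  semi-pos  positive  positivity
    1    1000       792       206         2      0.0020
    2     998       906        83         9      0.0090
    ...
referrals: 23  detected malignant: 2
```

— where round 1 is baseline; positivity is the fraction of scans referred
to the nodule clinic in that round, and the semi-positive fraction is
dominated by small sub-6.5 mm nodules returned to annual screening.

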
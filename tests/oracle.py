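"""Independent brute-force re-statement of the management decision table.

Used only as a cross-check oracle for the protocol engine.  Deliberately
written as one flat pass over literal constants, operating on plain dicts,
with no imports from the package: any disagreement with the engine points
at a real defect in one of the two.

A nodule scenario is a dict with keys:
    type      : "SOLID" | "PART_SOLID" | "NON_SOLID" | "ENDOBRONCHIAL" | "CALCIFIED"
    d, v      : overall average diameter (mm) / volume (mm3), or None
    sd, sv    : solid-component diameter / volume (part-solid only), or None
    new       : bool, first seen on this scan
    resolved  : bool
    growth    : "GROWING" | "SLOWLY_GROWING" | "STABLE" | "SHRINKING" | None
    vdt       : doubling time in days, or "NOT_GROWING", or None

The verdict is (category, action, interval_months, antibiotics) where
interval_months is None for referrals.
"""

REFER = "REFER_NODULE_CLINIC"
REPEAT = "REPEAT_LDCT"

_SEV = {"NEGATIVE": 0, "SEMI_POSITIVE": 1, "POSITIVE": 2}


def _size_at_least(nod, thr_mm, thr_mm3):
    # part-solid nodules are judged by their solid component when measured;
    # a measured volume overrides the diameter
    if nod["type"] == "PART_SOLID" and (nod.get("sd") is not None or nod.get("sv") is not None):
        d, v = nod.get("sd"), nod.get("sv")
    else:
        d, v = nod.get("d"), nod.get("v")
    if v is not None:
        return v >= thr_mm3
    if d is not None:
        return d >= thr_mm
    raise ValueError("unsized nodule")


def _followup_large(nod):
    if nod["type"] == "PART_SOLID" and (nod.get("sd") is not None or nod.get("sv") is not None):
        d, v = nod.get("sd"), nod.get("sv")
    else:
        d, v = nod.get("d"), nod.get("v")
    if v is not None:
        return v > 2000.0
    return d > 15.0


def _nodule_verdicts(context, nod):
    """Per-nodule verdicts: list of (severity, interval or None, antibiotics)."""
    t = nod["type"]
    if t == "CALCIFIED":
        return []
    if context == "BASELINE":
        if nod.get("resolved"):
            return []
        if t == "ENDOBRONCHIAL":
            return [(1, 1, False)]
        if t == "NON_SOLID":
            return [(1, 12, False)]
        if _size_at_least(nod, 15.5, 2000.0):
            return [(2, None, False)]
        if _size_at_least(nod, 6.5, 150.0):
            return [(1, 3, False)]
        return [(1, 12, False)]
    if context == "REPEAT":
        if nod.get("resolved"):
            return []
        is_new = bool(nod.get("new"))
        growth = nod.get("growth")
        vdt = nod.get("vdt")
        if t == "ENDOBRONCHIAL":
            return [(1, 1, False)] if is_new else [(2, None, False)]
        fast = isinstance(vdt, (int, float)) and vdt <= 365.0
        if t == "PART_SOLID" and not is_new and fast:
            return [(2, None, False)]
        if t == "NON_SOLID":
            if is_new or growth in ("GROWING", "SLOWLY_GROWING"):
                return [(1, 12, False)]
            return []
        # solid, or part-solid judged by component size
        if not (is_new or growth == "GROWING"):
            return []
        if _size_at_least(nod, 6.5, 150.0):
            return [(1, 1, True)]
        if _size_at_least(nod, 3.0, 20.0):
            return [(1, 6, False)]
        return [(1, 12, False)]
    if context == "FOLLOWUP":
        is_new = bool(nod.get("new"))
        if is_new:
            # no prior pair exists: the repeat-column new-nodule rules apply
            if nod.get("resolved"):
                return []
            if t == "ENDOBRONCHIAL":
                return [(1, 1, False)]
            if t == "NON_SOLID":
                return [(1, 12, False)]
            if _size_at_least(nod, 6.5, 150.0):
                return [(1, 1, True)]
            if _size_at_least(nod, 3.0, 20.0):
                return [(1, 6, False)]
            return [(1, 12, False)]
        if nod.get("resolved") or nod.get("growth") == "RESOLVED":
            return [(0, 24, False)]
        if t == "ENDOBRONCHIAL":
            return [(2, None, False)]
        vdt = nod.get("vdt")
        if vdt == "NOT_GROWING" or (isinstance(vdt, (int, float)) and vdt >= 600.0):
            return [(1, 12, False)]
        if vdt < 400.0:
            return [(2, None, False)]
        if _followup_large(nod):
            return [(2, None, False)]
        return [(1, 6, False)]
    raise ValueError(f"unknown context {context!r}")


def oracle_classify(context, nodules):
    """Classify one scan: (category, action, interval_months, antibiotics)."""
    verdicts = []
    for nod in nodules:
        verdicts.extend(_nodule_verdicts(context, nod))
    antibiotics = any(ab for _, _, ab in verdicts)
    if not verdicts:
        default = {"BASELINE": 12, "REPEAT": 24, "FOLLOWUP": 24}[context]
        return ("NEGATIVE", REPEAT, default, antibiotics)
    top = max(sev for sev, _, _ in verdicts)
    if top == 2:
        return ("POSITIVE", REFER, None, antibiotics)
    interval = min(iv for _, iv, _ in verdicts if iv is not None)
    category = {0: "NEGATIVE", 1: "SEMI_POSITIVE"}[top]
    return (category, REPEAT, interval, antibiotics)
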
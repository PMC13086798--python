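"""Unit tests for the decision-rule engine: every table cell, boundary
conventions, multi-nodule aggregation and round scheduling."""

import pytest

from lungscreen.engine import (
    RULES,
    Action,
    Category,
    classify_baseline,
    classify_followup,
    classify_repeat,
    classify_scan,
    next_round_type,
)
from lungscreen.nodule import (
    NOT_GROWING,
    GrowthAssessment,
    GrowthClass,
    NoduleObservation,
    NoduleType,
    ProtocolThresholds,
    RoundType,
    ScanContext,
)


def obs(ntype=NoduleType.SOLID, d=None, v=None, sd=None, sv=None, nid="n1", **kw):
    return NoduleObservation(
        nodule_id=nid, nodule_type=ntype, avg_diameter_mm=d, volume_mm3=v,
        solid_comp_diameter_mm=sd, solid_comp_volume_mm3=sv, **kw,
    )


def growth(cls, vdt=None):
    return GrowthAssessment(growth_class=cls, vdt_days=vdt)


STABLE = growth(GrowthClass.STABLE, NOT_GROWING)
GROWING_FAST = growth(GrowthClass.GROWING, 200.0)
GROWING_SLOWVDT = growth(GrowthClass.GROWING, 500.0)


class TestBaselineColumn:
    def test_no_nodules_is_negative_annual(self):
        c = classify_baseline([])
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.NEGATIVE, 12, "BL.a1",
        )

    def test_only_calcified_is_negative(self):
        c = classify_baseline([obs(NoduleType.CALCIFIED, d=20)])
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.NEGATIVE, 12, "BL.a1",
        )

    @pytest.mark.parametrize(
        "nodule, category, interval, code",
        [
            (dict(ntype=NoduleType.NON_SOLID, d=22), Category.SEMI_POSITIVE, 12, "BL.b1"),
            (dict(d=4), Category.SEMI_POSITIVE, 12, "BL.b2"),
            (dict(d=10), Category.SEMI_POSITIVE, 3, "BL.b3"),
            (dict(ntype=NoduleType.ENDOBRONCHIAL, d=5), Category.SEMI_POSITIVE, 1, "BL.b4"),
            (dict(d=16), Category.POSITIVE, None, "BL.c1"),
            (dict(ntype=NoduleType.PART_SOLID, d=12, sd=7), Category.SEMI_POSITIVE, 3, "BL.b3"),
            (dict(ntype=NoduleType.PART_SOLID, d=20, sd=4), Category.SEMI_POSITIVE, 12, "BL.b2"),
            (dict(ntype=NoduleType.PART_SOLID, d=25, sd=16), Category.POSITIVE, None, "BL.c1"),
        ],
    )
    def test_single_nodule_cells(self, nodule, category, interval, code):
        c = classify_baseline([obs(**nodule)])
        assert (c.category, c.interval_months, c.rule_code) == (category, interval, code)
        assert (c.action is Action.REFER_NODULE_CLINIC) == (category is Category.POSITIVE)

    @pytest.mark.parametrize(
        "d, code", [(6.4999, "BL.b2"), (6.5, "BL.b3"), (15.4999, "BL.b3"), (15.5, "BL.c1")]
    )
    def test_diameter_boundaries_closed_below(self, d, code):
        assert classify_baseline([obs(d=d)]).rule_code == code

    @pytest.mark.parametrize(
        "v, code", [(149.99, "BL.b2"), (150.0, "BL.b3"), (1999.99, "BL.b3"), (2000.0, "BL.c1")]
    )
    def test_volume_boundaries_closed_below(self, v, code):
        assert classify_baseline([obs(v=v)]).rule_code == code

    def test_volume_governs_when_diameter_disagrees(self):
        # 10 mm diameter suggests a 3-month recall, but the measured volume
        # is below the 150 mm3 criterion: the volumetric criterion governs.
        c = classify_baseline([obs(d=10, v=100)])
        assert (c.rule_code, c.interval_months) == ("BL.b2", 12)
        assert ("n1", "VOL.governs") in list(c.trace)

    def test_unsized_nodule_is_an_error(self):
        bad = NoduleObservation(
            nodule_id="n1", nodule_type=NoduleType.SOLID,
            avg_diameter_mm=5,
        )
        bad.__dict__["avg_diameter_mm"] = None  # bypass model validation
        with pytest.raises(ValueError):
            classify_baseline([bad])


class TestRepeatColumn:
    def test_all_stable_is_negative_biennial(self):
        pairs = [(obs(d=5, nid="a"), STABLE), (obs(d=8, nid="b"), STABLE)]
        c = classify_repeat(pairs)
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.NEGATIVE, 24, "RPT.a1",
        )

    @pytest.mark.parametrize(
        "d, interval, code, antibiotics",
        [
            (2, 12, "RPT.b2", False),
            (4, 6, "RPT.b3", False),
            (8, 1, "RPT.b4", True),
            (2.9999, 12, "RPT.b2", False),
            (3.0, 6, "RPT.b3", False),
            (6.5, 1, "RPT.b4", True),
        ],
    )
    def test_new_solid_size_bands(self, d, interval, code, antibiotics):
        c = classify_repeat([(obs(d=d, is_new=True), None)])
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.SEMI_POSITIVE, interval, code,
        )
        assert c.consider_antibiotics is antibiotics

    def test_growing_solid_uses_same_bands_as_new(self):
        c = classify_repeat([(obs(d=4), GROWING_SLOWVDT)])
        assert (c.interval_months, c.rule_code) == (6, "RPT.b3")

    def test_slowly_growing_solid_contributes_nothing(self):
        c = classify_repeat([(obs(d=10), growth(GrowthClass.SLOWLY_GROWING, 700.0))])
        assert (c.category, c.rule_code) == (Category.NEGATIVE, "RPT.a1")

    @pytest.mark.parametrize(
        "g", [growth(GrowthClass.SLOWLY_GROWING, 900.0), GROWING_SLOWVDT]
    )
    def test_non_solid_growth_returns_annual(self, g):
        c = classify_repeat([(obs(NoduleType.NON_SOLID, d=9), g)])
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.SEMI_POSITIVE, 12, "RPT.b1",
        )

    def test_new_endobronchial_one_month(self):
        c = classify_repeat([(obs(NoduleType.ENDOBRONCHIAL, d=4, is_new=True), None)])
        assert (c.interval_months, c.rule_code) == (1, "RPT.b5")

    def test_persistent_endobronchial_is_positive(self):
        c = classify_repeat([(obs(NoduleType.ENDOBRONCHIAL, d=4), STABLE)])
        assert (c.category, c.rule_code) == (Category.POSITIVE, "RPT.c2")

    def test_part_solid_doubling_within_year_is_positive(self):
        # a non-solid nodule that doubled within a year and now carries a
        # solid component presents as part-solid with VDT <= 365 d
        c = classify_repeat([(obs(NoduleType.PART_SOLID, d=9, sd=2), GROWING_FAST)])
        assert (c.category, c.rule_code) == (Category.POSITIVE, "RPT.c1")

    def test_non_solid_doubling_without_component_stays_semi_with_watch_flag(self):
        c = classify_repeat([(obs(NoduleType.NON_SOLID, d=9), GROWING_FAST)])
        assert (c.category, c.rule_code) == (Category.SEMI_POSITIVE, "RPT.b1")
        assert ("n1", "RPT.c1.watch") in list(c.trace)

    def test_missing_growth_assessment_is_an_error(self):
        with pytest.raises(ValueError, match="growth assessment"):
            classify_repeat([(obs(d=5), None)])


class TestFollowupColumn:
    @pytest.mark.parametrize(
        "vdt, d, category, interval, code",
        [
            (350, 10, Category.POSITIVE, None, "FU.c1"),
            (500, 10, Category.SEMI_POSITIVE, 6, "FU.b2"),
            (500, 16, Category.POSITIVE, None, "FU.c3"),
            (700, 10, Category.SEMI_POSITIVE, 12, "FU.b1"),
            (600, 10, Category.SEMI_POSITIVE, 12, "FU.b1"),  # 600 itself: annual cell
            (399.999, 10, Category.POSITIVE, None, "FU.c1"),
            (400, 10, Category.SEMI_POSITIVE, 6, "FU.b2"),
        ],
    )
    def test_vdt_bands(self, vdt, d, category, interval, code):
        c = classify_followup([(obs(d=d), growth(GrowthClass.GROWING, vdt))])
        assert (c.category, c.interval_months, c.rule_code) == (category, interval, code)

    def test_fifteen_mm_bound_is_strictly_larger_than(self):
        c = classify_followup([(obs(d=15.0), growth(GrowthClass.GROWING, 500))])
        assert c.rule_code == "FU.b2"
        c = classify_followup([(obs(d=15.01), growth(GrowthClass.GROWING, 500))])
        assert c.rule_code == "FU.c3"

    def test_resolved_nodule_negative_biennial(self):
        gone = obs(is_resolved=True)
        gone.__dict__["avg_diameter_mm"] = None
        c = classify_followup([(gone, growth(GrowthClass.RESOLVED))])
        assert (c.category, c.interval_months, c.rule_code) == (
            Category.NEGATIVE, 24, "FU.a1",
        )

    def test_not_growing_returns_to_annual(self):
        c = classify_followup([(obs(d=8), STABLE)])
        assert (c.interval_months, c.rule_code) == (12, "FU.b1")

    def test_persistent_endobronchial_positive(self):
        c = classify_followup([(obs(NoduleType.ENDOBRONCHIAL, d=5), STABLE)])
        assert (c.category, c.rule_code) == (Category.POSITIVE, "FU.c2")

    def test_missing_vdt_is_an_error(self):
        with pytest.raises(ValueError, match="VDT"):
            classify_followup([(obs(d=8), None)])


class TestAggregation:
    def test_max_severity_and_min_interval_win(self):
        c = classify_baseline(
            [obs(d=4, nid="small"), obs(d=10, nid="big"), obs(NoduleType.NON_SOLID, d=30, nid="gg")]
        )
        assert c.category is Category.SEMI_POSITIVE
        assert c.interval_months == 3
        assert c.driving_nodule_id == "big"

    def test_referral_dominates_everything(self):
        c = classify_baseline([obs(d=16, nid="big"), obs(d=4, nid="small")])
        assert c.category is Category.POSITIVE
        assert c.action is Action.REFER_NODULE_CLINIC
        assert c.interval_months is None
        assert c.driving_nodule_id == "big"

    @pytest.mark.parametrize(
        "base",
        [
            [],
            [obs(d=10, nid="a")],
            [obs(d=16, nid="a")],
            [obs(NoduleType.NON_SOLID, d=7, nid="a")],
        ],
    )
    def test_adding_a_calcified_nodule_never_changes_the_result(self, base):
        with_calc = base + [obs(NoduleType.CALCIFIED, d=25, nid="calc")]
        a, b = classify_baseline(base), classify_baseline(with_calc)
        assert (a.category, a.action, a.interval_months, a.rule_code) == (
            b.category, b.action, b.interval_months, b.rule_code,
        )

    def test_trace_records_every_triggered_rule(self):
        c = classify_baseline([obs(d=4, nid="a"), obs(d=10, nid="b")])
        assert ("a", "BL.b2") in list(c.trace) and ("b", "BL.b3") in list(c.trace)

    def test_every_rule_code_has_a_documented_cell(self):
        c = classify_baseline([obs(d=10)])
        assert all(code in RULES for _, code in c.trace)


class TestDispatchAndScheduling:
    def test_dispatch_matches_direct_calls(self):
        ctx = ScanContext(round_type=RoundType.BASELINE)
        assert classify_scan(ctx, []).rule_code == "BL.a1"
        ctx = ScanContext(round_type=RoundType.ANNUAL_REPEAT, days_since_prior=365)
        c = classify_scan(ctx, [obs(d=5)], {"n1": STABLE})
        assert c.rule_code == "RPT.a1"
        ctx = ScanContext(round_type=RoundType.INTERIM_FOLLOWUP, days_since_prior=90)
        c = classify_scan(ctx, [obs(d=8)], {"n1": growth(GrowthClass.GROWING, 350)})
        assert c.category is Category.POSITIVE

    def test_biennial_column_shares_annual_rules(self):
        annual = ScanContext(round_type=RoundType.ANNUAL_REPEAT, days_since_prior=365)
        biennial = ScanContext(round_type=RoundType.BIENNIAL_REPEAT, days_since_prior=730)
        for scan_obs, g in [([obs(d=4, is_new=True)], {}), ([obs(d=5)], {"n1": STABLE})]:
            a = classify_scan(annual, scan_obs, g)
            b = classify_scan(biennial, scan_obs, g)
            assert (a.category, a.interval_months, a.rule_code) == (
                b.category, b.interval_months, b.rule_code,
            )

    @pytest.mark.parametrize(
        "scan_obs, g, expected",
        [
            ([], {}, RoundType.ANNUAL_REPEAT),  # negative baseline: 12 mo
            ([obs(d=10)], {}, RoundType.INTERIM_FOLLOWUP),  # 3-mo recall
            ([obs(d=16)], {}, None),  # referral ends scheduling
        ],
    )
    def test_next_round_from_baseline(self, scan_obs, g, expected):
        ctx = ScanContext(round_type=RoundType.BASELINE)
        c = classify_scan(ctx, scan_obs, g)
        assert next_round_type(c, ctx) == expected

    def test_negative_repeat_moves_to_biennial(self):
        ctx = ScanContext(round_type=RoundType.ANNUAL_REPEAT, days_since_prior=365)
        c = classify_scan(ctx, [obs(d=5)], {"n1": STABLE})
        assert c.interval_months == 24
        assert next_round_type(c, ctx) is RoundType.BIENNIAL_REPEAT
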
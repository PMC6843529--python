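"""Monitoring event counts and fee-schedule billing."""

from decimal import Decimal
from types import MappingProxyType

import pytest
from hypothesis import given, settings, strategies as st

from ntmcost.catalog import ConfigurationError, ValidationError
from ntmcost.monitoring import (
    MonitoringSchedule,
    ScheduleParameters,
    amk_monitoring_addon,
    build_schedule,
    cost_schedule,
    monthly_physician_revenue,
    physician_revenue,
    published_line_overrides,
    published_monitoring_total,
    recomputed_monitoring_total,
)


class TestScheduleCounts:
    def test_fast_conversion_14_month_course(self):
        s = build_schedule(ScheduleParameters(14, 12, 2, amk_given=False))
        assert s["sputum_samples"] == 13
        assert s["xrays"] == 11
        assert s["ophtha_visits"] == 14
        assert s["ct_scans"] == 3
        assert s["lab_visits"] == 16
        assert s["quarters"] == 9
        assert s["audiometry"] == 0 and s["amk_levels"] == 0

    def test_slow_conversion_18_month_course(self):
        s = build_schedule(ScheduleParameters(18, 12, 6, amk_given=False))
        assert s["sputum_samples"] == 17
        assert s["xrays"] == 15
        assert s["ophtha_visits"] == 18
        assert s["ct_scans"] == 4
        assert s["lab_visits"] == 20
        assert s["quarters"] == 10

    def test_immediate_conversion_sputum_floor(self):
        assert build_schedule(ScheduleParameters(14, 12, 0))["sputum_samples"] == 11

    def test_amk_flag_adds_audiometry_and_levels(self):
        s = build_schedule(ScheduleParameters(14, 12, 2, amk_given=True))
        assert s["audiometry"] == 3 and s["amk_levels"] == 3

    def test_conversion_after_treatment_rejected(self):
        with pytest.raises(ValidationError):
            ScheduleParameters(treatment_months=4, conversion_months=6)

    @given(treatment=st.integers(6, 24), conversion=st.integers(0, 6))
    @settings(max_examples=50, deadline=None)
    def test_sputum_count_formula(self, treatment, conversion):
        """3 baseline + one per month until conversion + 8 post-conversion."""
        s = build_schedule(ScheduleParameters(treatment, 12, conversion))
        assert s["sputum_samples"] == 3 + conversion + 8

    def test_slow_minus_fast_conversion_is_four_sputum_sets(self):
        fast = build_schedule(ScheduleParameters(18, 12, 2))
        slow = build_schedule(ScheduleParameters(18, 12, 6))
        assert slow["sputum_samples"] - fast["sputum_samples"] == 4

    def test_idempotent(self):
        p = ScheduleParameters(18, 12, 6, amk_given=True)
        assert build_schedule(p).counts == build_schedule(p).counts


class TestCostSchedule:
    def test_published_line_totals(self, fee_schedule):
        cost = cost_schedule(build_schedule(ScheduleParameters(14, 12, 2)), fee_schedule)
        by_code = {l.code: l for l in cost.lines}
        assert by_code["EBM 32747"].line_total == Decimal("453.70")   # 13 cultures
        assert by_code["EBM 06212"].line_total == Decimal("227.22")   # 14 ophthalmology
        assert by_code["EBM 27320"].line_total == Decimal("0.00")     # ECG never billable

    def test_line_item_course_totals(self, fee_schedule):
        # the transparent fee-line sums; deliberately different from the
        # published course constants (2162.47 / 2895.75)
        t14 = recomputed_monitoring_total(ScheduleParameters(14, 12, 2), fee_schedule)
        t18 = recomputed_monitoring_total(ScheduleParameters(18, 12, 6), fee_schedule)
        assert t14 == Decimal("2389.29")
        assert t18 == Decimal("2895.35")

    def test_blood_count_published_override(self, fee_schedule):
        assert published_line_overrides(18) == {"EBM 32122": Decimal("22.20")}
        t18_exact = recomputed_monitoring_total(
            ScheduleParameters(18, 12, 6), fee_schedule, use_published_line_totals=False)
        assert t18_exact == Decimal("2895.15")        # 20 x 1.10 billed as 22.00

    def test_all_zero_schedule_bills_nothing(self, fee_schedule):
        empty = MonitoringSchedule(
            MappingProxyType({c: 0 for c in build_schedule(ScheduleParameters()).counts}),
            ScheduleParameters(),
        )
        cost = cost_schedule(empty, fee_schedule)
        assert cost.total == Decimal("0.00")

    def test_unconsumed_counter_rejected(self, fee_schedule):
        culled = [f for f in fee_schedule if f.frequency_role != "per_xray"]
        with pytest.raises(ConfigurationError, match="xrays"):
            cost_schedule(build_schedule(ScheduleParameters()), culled)

    def test_amk_addon_equals_with_minus_without(self, fee_schedule):
        base = ScheduleParameters(14, 12, 2, amk_given=False)
        with_amk = ScheduleParameters(14, 12, 2, amk_given=True)
        delta = (recomputed_monitoring_total(with_amk, fee_schedule)
                 - recomputed_monitoring_total(base, fee_schedule))
        assert delta == amk_monitoring_addon(fee_schedule)

    @given(scale=st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_total_monotone_in_counts(self, fee_schedule, scale):
        base = build_schedule(ScheduleParameters(14, 12, 2, amk_given=True))
        scaled = MonitoringSchedule(
            MappingProxyType({k: v * scale for k, v in base.counts.items()}),
            base.parameters,
        )
        assert cost_schedule(scaled, fee_schedule).total >= cost_schedule(base, fee_schedule).total


class TestPhysicianRevenue:
    @pytest.mark.parametrize("quarters,gp,pneumo", [
        (9, "517.14", "377.65"),
        (10, "574.60", "404.82"),
        (0, "0.00", "133.12"),   # once-off bronchoscopy + lavage remain
    ])
    def test_quarterly_revenue(self, fee_schedule, quarters, gp, pneumo):
        assert physician_revenue(quarters, fee_schedule) == (Decimal(gp), Decimal(pneumo))

    def test_negative_quarters_rejected(self, fee_schedule):
        with pytest.raises(ValueError):
            physician_revenue(-1, fee_schedule)

    @pytest.mark.parametrize("gp,pneumo,months,expected", [
        ("517.14", "377.65", 26, "34.42"),
        ("574.60", "404.82", 30, "32.65"),
        ("0", "0", 12, "0.00"),
    ])
    def test_monthly_revenue(self, gp, pneumo, months, expected):
        assert monthly_physician_revenue(Decimal(gp), Decimal(pneumo), months) == Decimal(expected)

    def test_zero_months_rejected(self):
        with pytest.raises(ValueError):
            monthly_physician_revenue(Decimal("1"), Decimal("1"), 0)


class TestAmkAddon:
    def test_addon_value(self, fee_schedule):
        assert amk_monitoring_addon(fee_schedule) == Decimal("100.83")

    @pytest.mark.parametrize("months,base,with_amk", [
        (14, "2162.47", "2263.30"),
        (18, "2895.75", "2996.58"),
    ])
    def test_published_constants_differ_by_addon(self, fee_schedule, months, base, with_amk):
        assert published_monitoring_total(months, False) == Decimal(base)
        assert published_monitoring_total(months, True) == Decimal(with_amk)
        assert Decimal(base) + amk_monitoring_addon(fee_schedule) == Decimal(with_amk)

    def test_missing_items_rejected(self, fee_schedule):
        culled = [f for f in fee_schedule if f.frequency_role != "per_amk_level"]
        with pytest.raises(ConfigurationError, match="per_amk_level"):
            amk_monitoring_addon(culled)
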
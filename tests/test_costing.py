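"""Salary conversion, capital annualization, overhead allocation and
commodity/test costing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from prepcost import reference
from prepcost import costing
from prepcost.costing import (
    CapitalItem,
    SalarySchedule,
    TestType,
    VisitCounts,
    allocate_overhead,
    annualize_capital,
    medication_cost,
    per_minute_cost,
    variable_personnel_cost,
)

# aliased so pytest does not try to collect library names as tests
eval_test_costs = costing.test_costs
eval_test_event_counts = costing.test_event_counts
from prepcost.ledger import CostCategory, ServiceModel
from prepcost.time_motion import Role


class TestSalaryConversion:
    @pytest.mark.parametrize(
        "annual,hourly",
        [
            (25_474.91, 12.25),  # research-program nurse
            (13_876.22, 6.67),  # public-sector nurse
            (2080.0, 1.00),  # the divisor is 2080 paid hours
        ],
    )
    def test_hourly_salary(self, annual, hourly):
        schedule = SalarySchedule({Role.NURSE: annual})
        assert schedule.hourly(Role.NURSE) == pytest.approx(hourly, abs=0.005)
        assert per_minute_cost(schedule, Role.NURSE) == pytest.approx(
            hourly / 60, abs=0.005 / 60
        )

    def test_unknown_role_is_lookup_error(self):
        schedule = SalarySchedule({Role.NURSE: 1000.0})
        with pytest.raises(KeyError, match="social_worker"):
            per_minute_cost(schedule, Role.SOCIAL_WORKER)


class TestCapitalAnnualization:
    def test_zero_rate_is_straight_line(self):
        assert annualize_capital(CapitalItem(300.0, 3, 0.0)) == pytest.approx(100.0)

    def test_three_year_annuity(self):
        # oracle: the discounted sum of the 3 annual payments returns the price
        payment = annualize_capital(CapitalItem(1000.0, 3, 0.03))
        assert payment == pytest.approx(353.53, abs=0.005)
        assert sum(payment * 1.03**-t for t in (1, 2, 3)) == pytest.approx(1000.0)

    def test_single_period(self):
        assert annualize_capital(CapitalItem(1000.0, 1, 0.03)) == pytest.approx(1030.0)

    @given(
        price=st.floats(min_value=1, max_value=1e6),
        life=st.integers(min_value=1, max_value=30),
        rate=st.floats(min_value=0.001, max_value=0.05),
    )
    def test_annuity_identity(self, price, life, rate):
        payment = annualize_capital(CapitalItem(price, life, rate))
        recovered = sum(payment * (1 + rate) ** -t for t in range(1, life + 1))
        assert recovered == pytest.approx(price, rel=1e-6)

    def test_continuous_at_zero_and_increasing_in_rate(self):
        base = annualize_capital(CapitalItem(1000.0, 3, 0.0))
        near = annualize_capital(CapitalItem(1000.0, 3, 1e-9))
        assert near == pytest.approx(base, rel=1e-6)
        rates = [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]
        values = [annualize_capital(CapitalItem(1000.0, 3, r)) for r in rates]
        assert values == sorted(values) and len(set(values)) == len(values)

    def test_rate_outside_supported_range_rejected(self):
        with pytest.raises(ValueError):
            CapitalItem(100.0, 3, -0.01)
        with pytest.raises(ValueError):
            CapitalItem(100.0, 3, 0.06)


class TestOverheadAllocation:
    @pytest.mark.parametrize("total,frac,expected", [(1000.0, 0.5, 500.0), (1000.0, 0.0, 0.0)])
    def test_proportional_allocation(self, total, frac, expected):
        assert allocate_overhead(total, frac) == expected

    def test_fraction_inverts_published_overhead(self):
        # with site overhead O, the fraction reproducing the published PrEP
        # overhead allocation is exactly published/O
        site_overhead = 50_000.0
        frac = 6822.96 / site_overhead
        assert allocate_overhead(site_overhead, frac) == pytest.approx(6822.96)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            allocate_overhead(100.0, 1.2)
        with pytest.raises(ValueError):
            allocate_overhead(100.0, -0.1)


STUDY = reference.STUDY_VISIT_COUNTS
ZERO = VisitCounts(0, 0, 0, 0, 0)


class TestTestCosts:
    def test_hbsag_initiations_only(self):
        costs = eval_test_costs(reference.TEST_SCHEDULE_DOH, STUDY)
        assert costs[TestType.HBSAG] == pytest.approx(603 * 10.12)
        # within 0.05% of the recorded public-sector HBsAg expenditure
        assert costs[TestType.HBSAG] == pytest.approx(6103.65, rel=5e-4)

    def test_hiv_initiation_plus_quarterlies(self):
        events = eval_test_event_counts(reference.TEST_SCHEDULE_DOH, STUDY)
        # back-derived public-sector HIV volume is ~773 tests, and every
        # initiator is tested at least once
        assert events[TestType.HIV] == STUDY.n_initiation + STUDY.n_quarterly
        assert events[TestType.HIV] >= 603
        assert events[TestType.HIV] == pytest.approx(3434.27 / 4.44, abs=1)

    def test_zero_visits_zero_costs(self):
        costs = eval_test_costs(reference.TEST_SCHEDULE_DOH, ZERO)
        assert all(v == 0.0 for v in costs.values())

    def test_omitted_tests_cost_nothing(self):
        costs = eval_test_costs(reference.TEST_SCHEDULE_DOH, STUDY)
        assert costs[TestType.SYPHILIS] == 0.0
        assert costs[TestType.CREATININE] == 0.0

    def test_linear_in_counts(self):
        double = VisitCounts(
            STUDY.n_initiation * 2,
            STUDY.n_monthly * 2,
            STUDY.n_quarterly * 2,
            STUDY.n_reminders * 2,
            STUDY.person_months * 2,
        )
        once = eval_test_costs(reference.TEST_SCHEDULE_DOH, STUDY)
        twice = eval_test_costs(reference.TEST_SCHEDULE_DOH, double)
        for t in TestType:
            assert twice[t] == pytest.approx(2 * once[t])

    def test_hiv_periodicity_beyond_quarter_rejected(self):
        with pytest.raises(ValueError):
            costing.TestSchedule({TestType.HIV: costing.TestRule(4.44, True, 6)})


class TestMedicationCost:
    def test_public_sector_price(self):
        cost = medication_cost(4.72, 1280)
        assert cost == pytest.approx(6041.60)
        assert cost == pytest.approx(6047.25, rel=1e-3)

    def test_zero_person_months(self):
        assert medication_cost(11.00, 0) == 0.0

    def test_as_implemented_price(self):
        assert medication_cost(11.00, 1280) == pytest.approx(14_080.0)
        assert medication_cost(11.00, 1280) == pytest.approx(14_080.41, rel=1e-4)


class TestVariablePersonnel:
    def test_single_initiation_hand_arithmetic(self, profile):
        counts = VisitCounts(1, 0, 0, 0, 1)
        schedule = reference.SALARIES_DOH[ServiceModel.STANDARD_CARE]
        nurse_rate = per_minute_cost(schedule, Role.NURSE)
        sw_rate = per_minute_cost(schedule, Role.SOCIAL_WORKER)
        expected = 34 * nurse_rate + 19 * sw_rate
        got = variable_personnel_cost(
            profile, counts, schedule, ServiceModel.STANDARD_CARE
        )
        assert got == pytest.approx(expected)

    def test_zero_visits_zero_cost(self, profile):
        schedule = reference.SALARIES_DOH[ServiceModel.CLUB]
        assert (
            variable_personnel_cost(profile, ZERO, schedule, ServiceModel.CLUB) == 0.0
        )

    @pytest.mark.parametrize(
        "salaries,recorded_key",
        [(reference.SALARIES_AS_IMPLEMENTED, "as_implemented"), (reference.SALARIES_DOH, "doh")],
    )
    def test_standard_care_within_5pct_of_recorded(self, profile, salaries, recorded_key):
        model = ServiceModel.STANDARD_CARE
        recorded = reference.ANNUAL_COSTS[(recorded_key, model)][
            CostCategory.PERSONNEL_VARIABLE
        ]
        got = variable_personnel_cost(profile, STUDY, salaries[model], model)
        assert got == pytest.approx(recorded, rel=0.05)

    def test_club_group_sessions_charged_per_group(self, profile):
        schedule = reference.SALARIES_DOH[ServiceModel.CLUB]
        counts = VisitCounts(0, 14, 0, 0, 14)
        got = variable_personnel_cost(profile, counts, schedule, ServiceModel.CLUB, group_size=7)
        nurse_rate = per_minute_cost(schedule, Role.NURSE)
        sw_rate = per_minute_cost(schedule, Role.SOCIAL_WORKER)
        # 14 clients = 2 full groups of 7: nurse per client, counsellor per group
        expected = 14 * 2 * nurse_rate + 2 * 41 * sw_rate
        assert got == pytest.approx(expected)

    def test_missing_cell_is_hard_error(self):
        from prepcost.time_motion import StaffTimeProfile

        empty = StaffTimeProfile(minutes={})
        schedule = reference.SALARIES_DOH[ServiceModel.CLUB]
        with pytest.raises(KeyError):
            variable_personnel_cost(empty, STUDY, schedule, ServiceModel.CLUB)


class TestUnitCostConsistency:
    """Variable annual costs reconcile with published per-person-month unit
    costs times the 1280-month denominator, to printed precision."""

    @pytest.mark.parametrize("scenario", ["as_implemented", "doh"])
    @pytest.mark.parametrize("model", list(ServiceModel))
    def test_variable_cost_equals_unit_times_person_months(self, scenario, model):
        column = reference.ANNUAL_COSTS[(scenario, model)]
        pm = reference.PERSON_MONTHS_STUDY
        for cat, annual in column.items():
            if annual is None or cat.behavior.value != "variable" or annual == 0:
                continue
            unit = round(annual / pm, 2)
            # printed units carry 2 decimals, so allow half a cent per month
            # on top of the 1% relative band
            assert abs(unit * pm - annual) <= max(0.01 * annual, 0.005 * pm + 0.005)
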
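"""Ingredients-based cost components for one service model in one scenario.

Personnel are costed per minute of observed service time: annual salary
(including allowances) divided by 260 working days of 8 hours — i.e. 2080
paid hours a year.  Capital purchases are annualized with the standard
annuity factor at a 3% discount rate over a 3-year useful life.  Laboratory
tests are unit cost times the number of test events implied by the visit
log and the testing schedule, and PrEP medication is the per-month supply
cost times person-months dispensed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

from prepcost.ledger import ServiceModel
from prepcost.time_motion import Role, StaffTimeProfile, VisitType

#: Paid working time per year assumed for salary-to-minute conversion.
WORKDAYS_PER_YEAR = 260
HOURS_PER_DAY = 8


@dataclass(frozen=True)
class SalarySchedule:
    """Annual salaries (USD, incl. allowances) by role, for one service model.

    ``hourly`` divides by workdays × hours (2080 by default, the standard
    full-time year excluding holidays and leave).
    """

    annual: Mapping[Role, float]
    workdays_per_year: int = WORKDAYS_PER_YEAR
    hours_per_day: float = HOURS_PER_DAY

    def __post_init__(self) -> None:
        if self.workdays_per_year <= 0 or self.hours_per_day <= 0:
            raise ValueError("workdays and hours per day must be positive")
        for role, salary in self.annual.items():
            if salary < 0:
                raise ValueError(f"negative salary for {role}: {salary}")

    def hourly(self, role: Role) -> float:
        return self._annual(role) / (self.workdays_per_year * self.hours_per_day)

    def _annual(self, role: Role) -> float:
        role = Role(role)
        try:
            return float(self.annual[role])
        except KeyError:
            raise KeyError(f"no salary on schedule for role {role.value!r}") from None


def per_minute_cost(schedule: SalarySchedule, role: Role) -> float:
    """Personnel cost per minute of paid time for ``role``."""
    return schedule.hourly(role) / 60.0


@dataclass(frozen=True)
class CapitalItem:
    """A capital purchase to be annualized over its useful life."""

    purchase_price: float
    useful_life_years: float = 3.0
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.purchase_price < 0:
            raise ValueError("purchase price cannot be negative")
        if self.useful_life_years <= 0:
            raise ValueError("useful life must be positive")
        if not (0.0 <= self.discount_rate <= 0.05):
            raise ValueError(
                f"discount rate {self.discount_rate} outside the supported 0-5% range"
            )


def annualize_capital(item: CapitalItem) -> float:
    """Equivalent annual cost of a capital item (annuity-factor method).

    price × r / (1 − (1 + r)^−life); the r → 0 limit is straight-line
    depreciation price/life.  The annuity identity holds by construction:
    the discounted sum of ``life`` annual payments equals the price.
    """
    price, life, r = item.purchase_price, item.useful_life_years, item.discount_rate
    if r == 0:
        return price / life
    annuity_factor = (1.0 - (1.0 + r) ** (-life)) / r
    return price / annuity_factor


def allocate_overhead(total_overhead: float, prep_activity_fraction: float) -> float:
    """Share of site overheads attributable to PrEP provision.

    The fraction is computed upstream as PrEP client activities (initiation,
    monthly and quarterly visits) over all client activities at the site.
    """
    if not (0.0 <= prep_activity_fraction <= 1.0):
        raise ValueError(
            f"activity fraction must lie in [0, 1], got {prep_activity_fraction}"
        )
    if total_overhead < 0:
        raise ValueError("overhead total cannot be negative")
    return total_overhead * prep_activity_fraction


class TestType(str, enum.Enum):
    HIV = "hiv_test"
    HBSAG = "hbsag_test"
    CREATININE = "creatinine_test"
    PREGNANCY = "pregnancy_test"
    SYPHILIS = "syphilis_test"


@dataclass(frozen=True)
class TestRule:
    """When a test is performed and at what unit cost (USD, incl. supplies)."""

    unit_cost: float
    required_at_initiation: bool = True
    #: Repeat interval in months; ``None`` means initiation-only.  A 3-month
    #: periodicity maps onto the quarterly refill visits.
    periodicity_months: int | None = None

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError("unit cost cannot be negative")
        if self.periodicity_months is not None and self.periodicity_months <= 0:
            raise ValueError("periodicity must be positive when present")


@dataclass(frozen=True)
class TestSchedule:
    """Map of test type to its rule; omitted tests cost nothing."""

    rules: Mapping[TestType, TestRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        hiv = self.rules.get(TestType.HIV)
        if hiv is not None and hiv.periodicity_months is not None:
            if hiv.periodicity_months > 3:
                raise ValueError(
                    "HIV retesting must occur at least every 3 months"
                )


@dataclass(frozen=True)
class VisitCounts:
    """Visit volumes over the costing year for one service model."""

    n_initiation: int
    n_monthly: int
    n_quarterly: int
    n_reminders: int
    person_months: int

    def __post_init__(self) -> None:
        for name in ("n_initiation", "n_monthly", "n_quarterly", "n_reminders", "person_months"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")

    @property
    def n_visits(self) -> int:
        return self.n_initiation + self.n_monthly + self.n_quarterly


def test_event_counts(
    schedule: TestSchedule, counts: VisitCounts
) -> dict[TestType, int]:
    """Number of test events implied by the visit volumes and the schedule.

    A test runs once per initiation if required at initiation, and once per
    quarterly refill visit if its periodicity is three months or less (blood
    draws happen at quarterly visits).
    """
    events: dict[TestType, int] = {t: 0 for t in TestType}
    for ttype, rule in schedule.rules.items():
        n = 0
        if rule.required_at_initiation:
            n += counts.n_initiation
        if rule.periodicity_months is not None and rule.periodicity_months <= 3:
            n += counts.n_quarterly
        events[TestType(ttype)] = n
    return events


def test_costs(schedule: TestSchedule, counts: VisitCounts) -> dict[TestType, float]:
    """Annual cost per test type: unit cost × number of test events."""
    events = test_event_counts(schedule, counts)
    return {
        ttype: events[ttype] * schedule.rules[ttype].unit_cost
        if ttype in schedule.rules
        else 0.0
        for ttype in TestType
    }


def medication_cost(unit_cost_per_month: float, person_months: float) -> float:
    """Annual PrEP drug cost: per-month supply cost × person-months dispensed."""
    if unit_cost_per_month < 0 or person_months < 0:
        raise ValueError("medication inputs cannot be negative")
    return unit_cost_per_month * person_months


def variable_personnel_cost(
    profile: StaffTimeProfile,
    counts: VisitCounts,
    schedule: SalarySchedule,
    model: ServiceModel,
    group_size: int = 7,
) -> float:
    """Annual service-delivery staff cost for one model.

    Sums, over visit types and roles, mean active minutes × per-minute salary
    × event count.  Club refill counselling is charged per group session:
    ⌈clients / group_size⌉ sessions at the per-group social-worker time.
    Reminder contacts (calls/texts) are charged once per follow-up contact at
    the social-worker rate.
    """
    model = ServiceModel(model)
    if group_size < 1:
        raise ValueError("group size must be at least 1")
    events: dict[VisitType, int] = {
        VisitType.INITIATION: counts.n_initiation,
        VisitType.MONTHLY_REFILL: counts.n_monthly,
        VisitType.QUARTERLY_REFILL: counts.n_quarterly,
        VisitType.REMINDER_CONTACT: counts.n_reminders,
    }
    total = 0.0
    for vtype, n_events in events.items():
        if n_events == 0:
            continue
        for role in Role:
            if vtype is VisitType.REMINDER_CONTACT and role is Role.NURSE:
                continue
            minutes = profile.get(model, vtype, role)  # KeyError if cell missing
            if profile.is_per_group(model, vtype, role):
                n_charged = math.ceil(n_events / group_size)
            else:
                n_charged = n_events
            total += minutes * per_minute_cost(schedule, role) * n_charged
    return total
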
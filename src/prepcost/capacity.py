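"""Bottleneck-constrained clinic throughput for the at-scale scenario.

The nurse and the social worker see each client in series — they cannot work
on different clients in parallel within a visit stream — so the daily client
ceiling is set by staff service time.  Two quantities are exposed:

* ``bottleneck`` — the cadre with the larger total service time across the
  three visit types (the printed "total time" row logic);
* ``daily_capacity`` — the maximum clients per day under the observed visit
  mix, with per-role ceilings reported alongside the combined (series)
  estimate, and annual person-month throughput under a one-month-per-visit
  dispensing rule.

The combined estimate divides the workday by the expected *total* staff
minutes per client (both cadres summed, club group-session time amortized
over the average group size), which is what the series assumption implies
when the two cadres cannot overlap.  Per-role ceilings (workday divided by
one cadre's expected minutes per client) are also reported; the standard-care
nurse ceiling, for example, is ⌊480 / (0.54×34 + 0.35×6 + 0.11×16)⌋ = 21
clients/day.

Published at-scale person-month volumes for this program were produced by a
spreadsheet whose internals are not available; this module is therefore a
documented, parameterized estimator, and the scenario engine takes at-scale
person-month volumes as inputs (defaulting to the published figures) rather
than deriving them here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from prepcost.costing import WORKDAYS_PER_YEAR
from prepcost.ledger import ServiceModel
from prepcost.time_motion import Role, StaffTimeProfile, VisitType

#: Productive minutes in a service day (8 hours, matching the salary basis).
DEFAULT_WORKDAY_MINUTES = 480.0

#: Clients per club counselling group session.
DEFAULT_GROUP_SIZE = 7

_CAPACITY_VISITS = (
    VisitType.INITIATION,
    VisitType.MONTHLY_REFILL,
    VisitType.QUARTERLY_REFILL,
)


@dataclass(frozen=True)
class VisitMix:
    """Shares of initiation / monthly / quarterly visits for one model."""

    initiation: float
    monthly: float
    quarterly: float

    def __post_init__(self) -> None:
        fracs = (self.initiation, self.monthly, self.quarterly)
        if any(f < 0 for f in fracs):
            raise ValueError("visit-mix fractions cannot be negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"visit-mix fractions must sum to 1, got {sum(fracs)}")

    def share(self, vtype: VisitType) -> float:
        return {
            VisitType.INITIATION: self.initiation,
            VisitType.MONTHLY_REFILL: self.monthly,
            VisitType.QUARTERLY_REFILL: self.quarterly,
        }[vtype]


@dataclass(frozen=True)
class CapacityEstimate:
    """Daily and annual throughput of one service model at full utilization."""

    model: ServiceModel
    bottleneck_role: Role
    clients_per_day: int
    clients_per_day_by_visit: Mapping[VisitType, float]
    clients_per_day_by_role: Mapping[Role, int]
    groups_per_day: Mapping[VisitType, float] | None
    annual_person_months: int
    workday_minutes: float
    workdays_per_year: int


def bottleneck(profile: StaffTimeProfile, model: ServiceModel) -> Role:
    """Cadre with the larger total service time across the three visit types.

    Per-group club cells enter at face value (the tabulated totals do the
    same).  Ties resolve to the nurse, the clinically constrained cadre.
    """
    model = ServiceModel(model)
    nurse = profile.role_total(model, Role.NURSE)
    social = profile.role_total(model, Role.SOCIAL_WORKER)
    return Role.SOCIAL_WORKER if social > nurse else Role.NURSE


def _expected_minutes_per_client(
    profile: StaffTimeProfile,
    mix: VisitMix,
    model: ServiceModel,
    role: Role,
    group_size: int,
) -> float:
    """Mix-weighted mean staff minutes per client for one cadre.

    Per-group cells are amortized over the average group size: over a year
    of operation groups fill to ``group_size``, so each client in a group
    visit consumes t_group / group_size social-worker minutes on average.
    """
    total = 0.0
    for vtype in _CAPACITY_VISITS:
        minutes = profile.get(model, vtype, role)
        if profile.is_per_group(model, vtype, role):
            minutes /= group_size
        total += mix.share(vtype) * minutes
    return total


def daily_capacity(
    profile: StaffTimeProfile,
    mix: VisitMix,
    model: ServiceModel,
    workday_minutes: float = DEFAULT_WORKDAY_MINUTES,
    group_size: int = DEFAULT_GROUP_SIZE,
    workdays_per_year: int = WORKDAYS_PER_YEAR,
) -> CapacityEstimate:
    """Maximum clients served per day and the implied annual person-months.

    The combined ceiling is ⌊workday / (nurse + social-worker expected
    minutes per client)⌋, reflecting strictly serial staffing; per-role
    ceilings ⌊workday / one cadre's expected minutes⌋ are reported in
    ``clients_per_day_by_role``.  Annual person-months assume every attended
    visit dispenses exactly one month of PrEP, ``workdays_per_year`` service
    days a year.

    A zero workday yields zero capacity; a profile with zero time for every
    cell is refused (capacity would be unbounded).
    """
    model = ServiceModel(model)
    if workday_minutes < 0:
        raise ValueError("workday cannot be negative")
    if group_size < 1:
        raise ValueError("group size must be at least 1")

    per_role = {
        role: _expected_minutes_per_client(profile, mix, model, role, group_size)
        for role in Role
    }
    combined = sum(per_role.values())
    if combined <= 0:
        raise ValueError(
            f"profile shows zero staff time per client for {model.value}; "
            "capacity is unbounded"
        )

    n_clients = int(math.floor(workday_minutes / combined))
    by_role = {
        role: (int(math.floor(workday_minutes / m)) if m > 0 else n_clients)
        for role, m in per_role.items()
    }
    by_visit = {vt: mix.share(vt) * n_clients for vt in _CAPACITY_VISITS}

    groups = None
    if any(profile.is_per_group(model, vt, Role.SOCIAL_WORKER) for vt in _CAPACITY_VISITS):
        groups = {
            vt: by_visit[vt] / group_size
            for vt in _CAPACITY_VISITS
            if profile.is_per_group(model, vt, Role.SOCIAL_WORKER)
        }

    return CapacityEstimate(
        model=model,
        bottleneck_role=bottleneck(profile, model),
        clients_per_day=n_clients,
        clients_per_day_by_visit=by_visit,
        clients_per_day_by_role=by_role,
        groups_per_day=groups,
        annual_person_months=n_clients * workdays_per_year,
        workday_minutes=workday_minutes,
        workdays_per_year=workdays_per_year,
    )
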
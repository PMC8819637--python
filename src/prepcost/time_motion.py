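"""Time-and-motion observation handling.

Observers time each staff member (nurse, social worker) through a service
visit, recording segments flagged as direct service, waiting for the client,
or research-specific activity.  Only service segments count toward costing:
``active_minutes`` strips waiting and research time.

Two distinct outputs are produced from the same observations, mirroring how
such studies are reported versus costed:

* ``summarize`` — medians and interquartile ranges of active visit time
  (both cadres combined), the reporting summary;
* ``build_profile`` — arithmetic mean active minutes per
  (service model, visit type, role) cell, the costing-grade profile that the
  personnel-cost engine multiplies by per-minute salaries.

Quartiles use linear interpolation between order statistics (the numpy
default), applied consistently everywhere.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from prepcost.ledger import ServiceModel

logger = logging.getLogger(__name__)


class VisitType(str, enum.Enum):
    INITIATION = "initiation"
    MONTHLY_REFILL = "monthly_refill"
    QUARTERLY_REFILL = "quarterly_refill"
    #: Scheduling calls / reminder texts ahead of a visit (social worker).
    REMINDER_CONTACT = "reminder_contact"


class Role(str, enum.Enum):
    NURSE = "nurse"
    SOCIAL_WORKER = "social_worker"


class SegmentFlag(str, enum.Enum):
    SERVICE = "service"
    WAITING = "waiting"
    RESEARCH = "research"


@dataclass(frozen=True)
class Segment:
    minutes: float
    flag: SegmentFlag = SegmentFlag.SERVICE

    def __post_init__(self) -> None:
        if self.minutes < 0 or not math.isfinite(self.minutes):
            raise ValueError(f"segment duration must be finite and >= 0: {self.minutes}")


@dataclass(frozen=True)
class TimeObservation:
    """One observed staff member during one visit.

    ``visit_id`` groups the nurse and social-worker observations of the same
    visit so that visit-level summaries can combine both cadres.  PrEP
    initiation follows the same procedure in every arm, so initiation
    observations are pooled across service models when building the profile.
    """

    service_model: ServiceModel
    visit_type: VisitType
    role: Role
    segments: tuple[Segment, ...]
    visit_id: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("observation has no segments")

    @property
    def active_minutes(self) -> float:
        return active_minutes(self)


def active_minutes(obs: TimeObservation) -> float:
    """Direct service time: the sum of service-flagged segments only."""
    return float(
        sum(s.minutes for s in obs.segments if s.flag is SegmentFlag.SERVICE)
    )


@dataclass(frozen=True)
class DurationSummary:
    """Median and interquartile range of a set of durations, in minutes."""

    median: float
    iqr_low: float
    iqr_high: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires at least one observation")
        if not (self.iqr_low <= self.median <= self.iqr_high):
            raise ValueError(
                f"inconsistent summary: Q1={self.iqr_low} median={self.median} "
                f"Q3={self.iqr_high}"
            )


def _summary(values: Sequence[float]) -> DurationSummary:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return DurationSummary(float(med), float(q1), float(q3), int(arr.size))


def summarize(
    observations: Iterable[TimeObservation],
    combine_roles: bool = True,
) -> dict[tuple[ServiceModel, VisitType], DurationSummary]:
    """Median/IQR of active visit time per (service model, visit type).

    With ``combine_roles`` (the default), the nurse and social-worker
    observations sharing a ``visit_id`` are summed into a single visit-level
    duration first, matching how visit times are reported.  Observations
    without a ``visit_id`` stand alone.  Initiation visits are pooled across
    service models and reported under every model.
    """
    obs = list(observations)
    per_visit: dict[tuple, float] = {}
    for i, o in enumerate(obs):
        model = o.service_model
        vid = o.visit_id if (combine_roles and o.visit_id is not None) else f"_anon{i}"
        key = (model, o.visit_type, vid)
        per_visit[key] = per_visit.get(key, 0.0) + active_minutes(o)

    grouped: dict[tuple[ServiceModel, VisitType], list[float]] = {}
    initiation_pool: list[float] = []
    for (model, vtype, _vid), total in per_visit.items():
        if vtype is VisitType.INITIATION:
            initiation_pool.append(total)
        else:
            grouped.setdefault((model, vtype), []).append(total)

    out: dict[tuple[ServiceModel, VisitType], DurationSummary] = {}
    if initiation_pool:
        s = _summary(initiation_pool)
        for model in ServiceModel:
            out[(model, VisitType.INITIATION)] = s
    for key, values in grouped.items():
        out[key] = _summary(values)
    return out


# (model, visit_type, role) cells where the social worker serves a whole
# group at once: club refill counselling sessions.
PER_GROUP_CELLS = frozenset(
    {
        (ServiceModel.CLUB, VisitType.MONTHLY_REFILL, Role.SOCIAL_WORKER),
        (ServiceModel.CLUB, VisitType.QUARTERLY_REFILL, Role.SOCIAL_WORKER),
    }
)


@dataclass(frozen=True)
class StaffTimeProfile:
    """Mean active minutes per (service model, visit type, role) cell.

    Club refill counselling is delivered to a whole group at once, so those
    social-worker cells are minutes *per group*; every other cell is minutes
    per client.  ``per_group`` marks the per-group cells explicitly.
    """

    minutes: Mapping[tuple[ServiceModel, VisitType, Role], float]
    per_group: frozenset[tuple[ServiceModel, VisitType, Role]] = field(
        default=PER_GROUP_CELLS
    )

    def __post_init__(self) -> None:
        for cell, value in self.minutes.items():
            if value < 0:
                raise ValueError(f"negative mean minutes for cell {cell}: {value}")

    def get(self, model: ServiceModel, vtype: VisitType, role: Role) -> float:
        """Mean minutes for a cell; raises ``KeyError`` naming missing cells."""
        key = (ServiceModel(model), VisitType(vtype), Role(role))
        try:
            return float(self.minutes[key])
        except KeyError:
            raise KeyError(
                f"no observed time for cell (model={key[0].value}, "
                f"visit={key[1].value}, role={key[2].value})"
            ) from None

    def is_per_group(self, model: ServiceModel, vtype: VisitType, role: Role) -> bool:
        return (ServiceModel(model), VisitType(vtype), Role(role)) in self.per_group

    def missing_cells(
        self, model: ServiceModel, visit_types: Iterable[VisitType] | None = None
    ) -> list[tuple[ServiceModel, VisitType, Role]]:
        vtypes = list(visit_types) if visit_types is not None else list(VisitType)
        out = []
        for vt in vtypes:
            for role in Role:
                if vt is VisitType.REMINDER_CONTACT and role is Role.NURSE:
                    continue  # reminders are a social-worker activity
                if (ServiceModel(model), vt, role) not in self.minutes:
                    out.append((ServiceModel(model), vt, role))
        return out

    def role_total(self, model: ServiceModel, role: Role) -> float:
        """Summed mean minutes across the three visit types for one cadre.

        Per-group cells enter at face value, matching how total service time
        per day is tabulated; reminder contacts are excluded.
        """
        total = 0.0
        for vt in (VisitType.INITIATION, VisitType.MONTHLY_REFILL, VisitType.QUARTERLY_REFILL):
            total += self.get(model, vt, role)
        return total


def build_profile(observations: Iterable[TimeObservation]) -> StaffTimeProfile:
    """Arithmetic mean active minutes per cell from raw observations.

    Initiation observations are pooled across service models (one procedure
    in all arms) and the pooled mean is written into every model's initiation
    cells.
    """
    sums: dict[tuple[ServiceModel, VisitType, Role], float] = {}
    counts: dict[tuple[ServiceModel, VisitType, Role], int] = {}
    init_sums: dict[Role, float] = {}
    init_counts: dict[Role, int] = {}
    for o in observations:
        if o.visit_type is VisitType.INITIATION:
            init_sums[o.role] = init_sums.get(o.role, 0.0) + active_minutes(o)
            init_counts[o.role] = init_counts.get(o.role, 0) + 1
            continue
        key = (o.service_model, o.visit_type, o.role)
        sums[key] = sums.get(key, 0.0) + active_minutes(o)
        counts[key] = counts.get(key, 0) + 1

    minutes = {key: sums[key] / counts[key] for key in sums}
    for role, total in init_sums.items():
        mean = total / init_counts[role]
        for model in ServiceModel:
            minutes[(model, VisitType.INITIATION, role)] = mean
    return StaffTimeProfile(minutes=minutes)


def read_observations(path) -> list[TimeObservation]:
    """Read an observation CSV (one row per timed segment).

    Columns: ``model,visit_type,role,minutes,flag`` plus ``obs_id`` grouping
    segments into observations and an optional ``visit_id`` pairing the two
    cadres' observations of one visit.
    """
    frame = pd.read_csv(path, dtype=str)
    required = {"model", "visit_type", "role", "minutes", "flag", "obs_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"observation file missing columns: {sorted(missing)}")
    has_visit = "visit_id" in frame.columns
    groups: dict[str, dict] = {}
    for row in frame.itertuples(index=False):
        rec = groups.setdefault(
            str(row.obs_id),
            {
                "model": ServiceModel(row.model),
                "visit_type": VisitType(row.visit_type),
                "role": Role(row.role),
                "visit_id": str(row.visit_id) if has_visit else None,
                "segments": [],
            },
        )
        rec["segments"].append(Segment(float(row.minutes), SegmentFlag(row.flag)))
    return [
        TimeObservation(
            service_model=rec["model"],
            visit_type=rec["visit_type"],
            role=rec["role"],
            segments=tuple(rec["segments"]),
            visit_id=rec["visit_id"],
        )
        for rec in groups.values()
    ]


def write_observations(observations: Iterable[TimeObservation], path) -> None:
    """Write observations in the CSV schema read by :func:`read_observations`."""
    rows = []
    for i, o in enumerate(observations):
        for seg in o.segments:
            rows.append(
                {
                    "obs_id": f"obs{i:04d}",
                    "visit_id": o.visit_id if o.visit_id is not None else "",
                    "model": o.service_model.value,
                    "visit_type": o.visit_type.value,
                    "role": o.role.value,
                    "minutes": repr(seg.minutes),
                    "flag": seg.flag.value,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
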
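"""Seeded synthetic-data generators emulating the program's raw inputs.

Raw observation logs, the participant visit log and itemized expenditure
ledgers from the costed program are not published; these generators produce
data with the statistical structure the pipeline assumes, calibrated to the
published summary statistics, so every stage can be exercised end to end.

* ``gen_enrolment`` — a per-participant visit log.  Retention has three
  parts: a share of initiators never return (putting the median time on
  PrEP at one month); returners stay in the program for a geometric number
  of months (the on-program window); and each scheduled visit inside the
  window is attended with a fixed probability (visits are commonly skipped
  and clients return later).  The defaults are calibrated jointly to the
  published summaries: mean 2.123 months on PrEP (1280 person-months over
  603 initiators), median 1 (IQR upper bound ≤ 3), and a follow-up stream
  of roughly 500 monthly and 175 quarterly refills.  Follow-up visits fall
  on the program calendar: monthly refills at months 1, 2, 4, 5, 7, 8, 10
  and 11; quarterly (blood-test) refills at months 3, 6, 9 and 12.
* ``gen_observations`` — time-and-motion observations with log-normal
  service durations located at the reported medians (right-skewed, like the
  reported interquartile ranges) plus waiting and research segments that the
  pipeline must strip.
* ``gen_ledger`` — itemized ledger entries whose category sums reproduce
  configured annual totals exactly (conservation by construction).

All generators are pure functions of their configuration, including the
seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from prepcost import reference
from prepcost.costing import VisitCounts
from prepcost.ledger import (
    COSTING_WINDOW,
    CostCategory,
    Currency,
    LedgerEntry,
    Money,
    ServiceModel,
)
from prepcost.time_motion import (
    Role,
    Segment,
    SegmentFlag,
    TimeObservation,
    VisitType,
)

_MODELS = tuple(ServiceModel)

#: Default per-role median service minutes for generated observations,
#: consistent with the reported visit-level medians (initiation 51 = 32
#: nurse + 19 social worker, standard monthly 6, club quarterly 57, ...).
DEFAULT_DURATION_TARGETS: dict[tuple[ServiceModel | None, VisitType, Role], float] = {
    (None, VisitType.INITIATION, Role.NURSE): 32.0,
    (None, VisitType.INITIATION, Role.SOCIAL_WORKER): 19.0,
    (ServiceModel.STANDARD_CARE, VisitType.MONTHLY_REFILL, Role.NURSE): 5.0,
    (ServiceModel.STANDARD_CARE, VisitType.MONTHLY_REFILL, Role.SOCIAL_WORKER): 1.0,
    (ServiceModel.STANDARD_CARE, VisitType.QUARTERLY_REFILL, Role.NURSE): 16.0,
    (ServiceModel.STANDARD_CARE, VisitType.QUARTERLY_REFILL, Role.SOCIAL_WORKER): 1.0,
    (ServiceModel.CLUB, VisitType.MONTHLY_REFILL, Role.NURSE): 2.0,
    (ServiceModel.CLUB, VisitType.MONTHLY_REFILL, Role.SOCIAL_WORKER): 41.0,
    (ServiceModel.CLUB, VisitType.QUARTERLY_REFILL, Role.NURSE): 19.0,
    (ServiceModel.CLUB, VisitType.QUARTERLY_REFILL, Role.SOCIAL_WORKER): 38.0,
    (ServiceModel.INDIVIDUAL, VisitType.MONTHLY_REFILL, Role.NURSE): 5.0,
    (ServiceModel.INDIVIDUAL, VisitType.MONTHLY_REFILL, Role.SOCIAL_WORKER): 25.0,
    (ServiceModel.INDIVIDUAL, VisitType.QUARTERLY_REFILL, Role.NURSE): 20.0,
    (ServiceModel.INDIVIDUAL, VisitType.QUARTERLY_REFILL, Role.SOCIAL_WORKER): 26.0,
    (None, VisitType.REMINDER_CONTACT, Role.SOCIAL_WORKER): 2.0,
}

#: Observation counts emulating the study's 50 time-and-motion observations
#: (9 initiation visits plus 15 / 8 / 18 follow-up visits by arm), with
#: follow-ups split roughly 2:1 monthly:quarterly.
DEFAULT_OBSERVATION_COUNTS: dict[tuple[ServiceModel | None, VisitType], int] = {
    (None, VisitType.INITIATION): 9,
    (ServiceModel.STANDARD_CARE, VisitType.MONTHLY_REFILL): 10,
    (ServiceModel.STANDARD_CARE, VisitType.QUARTERLY_REFILL): 5,
    (ServiceModel.CLUB, VisitType.MONTHLY_REFILL): 5,
    (ServiceModel.CLUB, VisitType.QUARTERLY_REFILL): 3,
    (ServiceModel.INDIVIDUAL, VisitType.MONTHLY_REFILL): 12,
    (ServiceModel.INDIVIDUAL, VisitType.QUARTERLY_REFILL): 6,
}


def _default_ledger_targets() -> dict:
    """As-implemented annual totals: fixed categories shared, variable per model."""
    shared = {
        cat: val
        for cat, val in reference.ANNUAL_COSTS[
            ("as_implemented", ServiceModel.CLUB)
        ].items()
        if val is not None and cat.behavior.value == "fixed"
    }
    per_model = {
        model: {
            cat: val
            for cat, val in reference.ANNUAL_COSTS[("as_implemented", model)].items()
            if val is not None and val > 0 and cat.behavior.value == "variable"
        }
        for model in _MODELS
    }
    return {"shared": shared, "per_model": per_model}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for all three generators; defaults emulate the study conditions."""

    seed: int = 0
    n_participants: int = reference.N_INITIATORS
    #: Probability an initiator never returns after the initiation month.
    month1_stop_prob: float = 0.40
    #: Month-to-month continuation of the on-program window among returners.
    window_continuation_prob: float = 0.80
    #: Probability each scheduled visit inside the window is attended.  The
    #: three defaults jointly put the mean time on PrEP at 2.123 months with
    #: median 1 and the observed monthly/quarterly follow-up composition.
    visit_attendance_prob: float = 0.402
    max_months: int = 12
    #: Optional per-arm retention overrides:
    #: model -> (stop, window continuation, attendance).
    retention_overrides: Mapping[ServiceModel, tuple[float, float, float]] = field(
        default_factory=dict
    )
    duration_targets: Mapping[tuple[ServiceModel | None, VisitType, Role], float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_TARGETS)
    )
    #: Log-scale spread of generated service durations (log-normal shape).
    duration_sigma: float = 0.3
    observation_counts: Mapping[tuple[ServiceModel | None, VisitType], int] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVATION_COUNTS)
    )
    #: Extra reminder-contact timings (outside the 50 visit observations).
    n_reminder_obs: int = 10
    ledger_targets: Mapping = field(default_factory=_default_ledger_targets)
    #: Ledger entries per category target (1-10 way random splits).
    max_ledger_splits: int = 10

    def __post_init__(self) -> None:
        probs = (
            self.month1_stop_prob,
            self.window_continuation_prob,
            self.visit_attendance_prob,
        )
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"retention probability outside [0, 1]: {p}")
        if self.n_participants < 0:
            raise ValueError("n_participants cannot be negative")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _visit_type_for_month(month: int) -> VisitType:
    if month in reference.QUARTERLY_VISIT_MONTHS:
        return VisitType.QUARTERLY_REFILL
    return VisitType.MONTHLY_REFILL


def gen_enrolment(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the participant visit log.

    Returns a frame with columns ``participant_id, model, month, visit_type``
    — one row per attended dispensing visit (month 0 is initiation).  Arms
    are allocated 1:1:1.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for i in range(config.n_participants):
        model = _MODELS[i % 3]
        stop, cont, attend = config.retention_overrides.get(
            model,
            (
                config.month1_stop_prob,
                config.window_continuation_prob,
                config.visit_attendance_prob,
            ),
        )
        rows.append(
            {
                "participant_id": f"p{i:04d}",
                "model": model.value,
                "month": 0,
                "visit_type": VisitType.INITIATION.value,
            }
        )
        if rng.random() < stop:
            continue
        window = 1
        while window < config.max_months and rng.random() < cont:
            window += 1
        for month in range(1, window + 1):
            if rng.random() < attend:
                rows.append(
                    {
                        "participant_id": f"p{i:04d}",
                        "model": model.value,
                        "month": month,
                        "visit_type": _visit_type_for_month(month).value,
                    }
                )
    return pd.DataFrame(rows, columns=["participant_id", "model", "month", "visit_type"])


def person_months(log: pd.DataFrame) -> int:
    """Total person-months dispensed: one per attended visit."""
    return int(len(log))


def durations_months(log: pd.DataFrame) -> pd.Series:
    """Months of PrEP per participant (dispensing events attended)."""
    return log.groupby("participant_id").size()


def visit_counts_from_log(
    log: pd.DataFrame, model: ServiceModel | None = None
) -> VisitCounts:
    """Visit volumes (pooled, or for one model) implied by a visit log.

    One reminder contact is assumed per attended visit, and each visit
    dispenses one month of PrEP.
    """
    if model is not None:
        log = log[log["model"] == ServiceModel(model).value]
    counts = log["visit_type"].value_counts()
    n_init = int(counts.get(VisitType.INITIATION.value, 0))
    n_mon = int(counts.get(VisitType.MONTHLY_REFILL.value, 0))
    n_qtr = int(counts.get(VisitType.QUARTERLY_REFILL.value, 0))
    total = n_init + n_mon + n_qtr
    return VisitCounts(
        n_initiation=n_init,
        n_monthly=n_mon,
        n_quarterly=n_qtr,
        n_reminders=total,
        person_months=total,
    )


def _lognormal_minutes(rng: np.random.Generator, median: float, sigma: float) -> float:
    if median == 0:
        return 0.0
    return float(median * np.exp(sigma * rng.standard_normal()))


def gen_observations(config: GeneratorConfig) -> list[TimeObservation]:
    """Generate time-and-motion observations.

    Each observed visit yields one nurse and one social-worker observation
    sharing a ``visit_id``; service durations are log-normal around the
    configured per-role medians, and every observation carries waiting and
    research segments that ``active_minutes`` must exclude.  Initiation
    visits rotate through the three arms (the procedure is identical).
    """
    rng = np.random.default_rng(config.seed + 1)
    observations: list[TimeObservation] = []
    vid = 0

    def targets(model, vtype, role) -> float | None:
        t = config.duration_targets.get((model, vtype, role))
        if t is None:
            t = config.duration_targets.get((None, vtype, role))
        return t

    for (model, vtype), n in config.observation_counts.items():
        for j in range(n):
            obs_model = model if model is not None else _MODELS[(vid + j) % 3]
            visit_id = f"v{vid:04d}"
            vid += 1
            for role in (Role.NURSE, Role.SOCIAL_WORKER):
                median = targets(model, vtype, role)
                if median is None:
                    continue
                service = _lognormal_minutes(rng, median, config.duration_sigma)
                segments = (
                    Segment(service, SegmentFlag.SERVICE),
                    Segment(float(rng.uniform(2, 15)), SegmentFlag.WAITING),
                    Segment(float(rng.uniform(1, 10)), SegmentFlag.RESEARCH),
                )
                observations.append(
                    TimeObservation(
                        service_model=obs_model,
                        visit_type=vtype,
                        role=role,
                        segments=segments,
                        visit_id=visit_id,
                    )
                )

    for j in range(config.n_reminder_obs):
        model = _MODELS[j % 3]
        median = targets(None, VisitType.REMINDER_CONTACT, Role.SOCIAL_WORKER)
        service = _lognormal_minutes(rng, float(median), config.duration_sigma)
        observations.append(
            TimeObservation(
                service_model=model,
                visit_type=VisitType.REMINDER_CONTACT,
                role=Role.SOCIAL_WORKER,
                segments=(Segment(service, SegmentFlag.SERVICE),),
                visit_id=f"r{j:04d}",
            )
        )
    return observations


def _split_amount(
    rng: np.random.Generator, total: float, max_splits: int
) -> list[float]:
    """Split ``total`` into 1-max_splits parts that sum back exactly."""
    k = int(rng.integers(1, max_splits + 1))
    if k == 1 or total == 0:
        return [total]
    cuts = np.sort(rng.uniform(0, total, size=k - 1))
    parts = np.diff(np.concatenate([[0.0], cuts, [total]])).tolist()
    parts[-1] = total - sum(parts[:-1])  # exact conservation
    return [float(p) for p in parts]


def gen_ledger(config: GeneratorConfig) -> list[LedgerEntry]:
    """Generate itemized ledger entries matching configured category totals.

    Shared (site-level) targets become shared entries; per-model targets
    become model-tagged entries.  Per category, the total is split into a
    random number of dated items whose sum is exact by construction.
    """
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = COSTING_WINDOW
    span = (hi - lo).days
    entries: list[LedgerEntry] = []

    def emit(cat: CostCategory, total: float, model: ServiceModel | None) -> None:
        for part in _split_amount(rng, float(total), config.max_ledger_splits):
            date = lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))
            entries.append(
                LedgerEntry(
                    date=date,
                    category=cat,
                    amount=Money(part, Currency.USD),
                    service_model=model,
                )
            )

    for cat, total in config.ledger_targets.get("shared", {}).items():
        emit(CostCategory(cat), total, None)
    for model, cats in config.ledger_targets.get("per_model", {}).items():
        for cat, total in cats.items():
            emit(CostCategory(cat), total, ServiceModel(model))
    return entries
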
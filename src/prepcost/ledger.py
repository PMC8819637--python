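"""Domain types for program expenditure records and the fixed/variable taxonomy.

The costing pipeline works in 2020 US dollars.  Field expenditures are
recorded in South African Rand (ZAR) and converted at the study-period
average market rate of 14.31 ZAR per USD.  Monetary arithmetic is carried at
full floating-point precision; rounding to cents happens only when a report
is rendered.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

#: Study-period average market exchange rate (ZAR per USD).
DEFAULT_ZAR_PER_USD = 14.31

#: Costing window: one program year.
COSTING_WINDOW = (_dt.date(2018, 11, 1), _dt.date(2019, 11, 1))


class Currency(str, enum.Enum):
    ZAR = "ZAR"
    USD = "USD"


class CostBehavior(str, enum.Enum):
    """Whether a cost scales with client volume."""

    FIXED = "fixed"
    VARIABLE = "variable"


class CostCategory(str, enum.Enum):
    """Program cost categories.

    The first six are fixed (independent of client volume: start-up capital,
    training, demand creation, supervisory personnel, site overheads and
    monitoring/evaluation supplies).  The remainder are variable, scaling
    with visits and person-months (service-delivery staff time, PrEP drug,
    consumables and laboratory tests).
    """

    CAPITAL = "capital"
    TRAINING = "training"
    DEMAND_CREATION = "demand_creation"
    PERSONNEL_FIXED = "personnel_fixed"
    OVERHEAD = "overhead"
    ADMIN_SUPPLIES = "admin_supplies"
    PERSONNEL_VARIABLE = "personnel_variable"
    PREP_MEDICATION = "prep_medication"
    MISC_MEDICAL_SUPPLIES = "misc_medical_supplies"
    HIV_TEST = "hiv_test"
    HBSAG_TEST = "hbsag_test"
    CREATININE_TEST = "creatinine_test"
    PREGNANCY_TEST = "pregnancy_test"
    SYPHILIS_TEST = "syphilis_test"

    @property
    def behavior(self) -> CostBehavior:
        if self in _FIXED_CATEGORIES:
            return CostBehavior.FIXED
        return CostBehavior.VARIABLE


_FIXED_CATEGORIES = frozenset(
    {
        CostCategory.CAPITAL,
        CostCategory.TRAINING,
        CostCategory.DEMAND_CREATION,
        CostCategory.PERSONNEL_FIXED,
        CostCategory.OVERHEAD,
        CostCategory.ADMIN_SUPPLIES,
    }
)

FIXED_CATEGORIES: tuple[CostCategory, ...] = tuple(
    c for c in CostCategory if c.behavior is CostBehavior.FIXED
)
VARIABLE_CATEGORIES: tuple[CostCategory, ...] = tuple(
    c for c in CostCategory if c.behavior is CostBehavior.VARIABLE
)


class ServiceModel(str, enum.Enum):
    """The three PrEP service-delivery models (trial arms).

    ``standard_care``: community-based dispensary with passive adherence
    support; ``club``: group-based effective-use counselling; ``individual``:
    one-on-one effective-use counselling.
    """

    STANDARD_CARE = "standard_care"
    CLUB = "club"
    INDIVIDUAL = "individual"


@dataclass(frozen=True)
class Money:
    """A non-negative amount of money tagged with its currency."""

    amount: float
    currency: Currency = Currency.USD

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"costs cannot be negative: {self.amount}")


def convert_currency(
    money: Money, target: Currency, rate: float = DEFAULT_ZAR_PER_USD
) -> Money:
    """Convert ``money`` to ``target`` currency at ``rate`` ZAR per USD.

    Conversion is exact division/multiplication; a round trip recovers the
    original amount to floating-point precision.

    Raises
    ------
    ValueError
        If ``rate`` is not strictly positive.
    """
    if not rate > 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    target = Currency(target)
    if money.currency is target:
        return money
    if target is Currency.USD:  # ZAR -> USD
        return Money(money.amount / rate, Currency.USD)
    return Money(money.amount * rate, Currency.ZAR)  # USD -> ZAR


@dataclass(frozen=True)
class LedgerEntry:
    """One dated expenditure record.

    ``service_model`` is ``None`` for shared (site-level) entries, which are
    attributable in full to each of the three service models: the costing
    question is "what would the program cost if run entirely under this
    model", so site-level fixed costs appear identically in every model's
    column.
    """

    date: _dt.date
    category: CostCategory
    amount: Money
    service_model: ServiceModel | None = None

    def __post_init__(self) -> None:
        lo, hi = COSTING_WINDOW
        if not (lo <= self.date <= hi):
            raise ValueError(
                f"ledger entry dated {self.date} outside costing window "
                f"[{lo}, {hi}]"
            )


def aggregate_ledger(
    entries: Iterable[LedgerEntry],
    model: ServiceModel,
    rate: float = DEFAULT_ZAR_PER_USD,
) -> dict[CostCategory, float]:
    """Sum ledger entries into per-category annual USD totals for one model.

    Shared entries (``service_model is None``) count toward every model;
    model-specific entries count only toward their own model.  ZAR amounts
    are converted at ``rate``.  Every category appears in the result (zero if
    no entries), so downstream code never needs to special-case absent keys.
    """
    model = ServiceModel(model)
    totals: dict[CostCategory, float] = {c: 0.0 for c in CostCategory}
    for entry in entries:
        if entry.service_model is not None and entry.service_model is not model:
            continue
        usd = convert_currency(entry.amount, Currency.USD, rate)
        totals[entry.category] += usd.amount
    return totals


def read_ledger(path) -> list[LedgerEntry]:
    """Read a ledger CSV with columns date,category,amount,currency,service_model.

    ``service_model`` may be one of the three model ids or ``shared``.
    Unknown categories raise ``ValueError`` naming the offending string.
    """
    frame = pd.read_csv(path, dtype=str)
    required = {"date", "category", "amount", "currency", "service_model"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"ledger file missing columns: {sorted(missing)}")
    entries: list[LedgerEntry] = []
    for row in frame.itertuples(index=False):
        try:
            category = CostCategory(row.category)
        except ValueError as exc:
            raise ValueError(f"unknown cost category {row.category!r}") from exc
        model_str = str(row.service_model).strip().lower()
        model = None if model_str == "shared" else ServiceModel(model_str)
        entries.append(
            LedgerEntry(
                date=_dt.date.fromisoformat(str(row.date)),
                category=category,
                amount=Money(float(row.amount), Currency(row.currency)),
                service_model=model,
            )
        )
    return entries


def write_ledger(entries: Iterable[LedgerEntry], path) -> None:
    """Write entries in the CSV schema accepted by :func:`read_ledger`."""
    rows = [
        {
            "date": e.date.isoformat(),
            "category": e.category.value,
            "amount": repr(e.amount.amount),
            "currency": e.amount.currency.value,
            "service_model": "shared" if e.service_model is None else e.service_model.value,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def totals_by_category(totals: Mapping[CostCategory, float]) -> float:
    """Grand total of a per-category cost map."""
    return float(sum(totals.values()))
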
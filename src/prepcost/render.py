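"""Presentation-layer renderers for cost columns and duration summaries.

JSON (via ``CostReport.to_dict``) is the machine interface; the functions
here produce the human-facing tables: the nine-column annual/unit cost
table, the staff-time capacity table and "median (IQR: lo, hi)" duration
lines.  Money is rounded to cents only here, at the report boundary, and an
em-dash marks categories excluded from a scenario.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from prepcost.capacity import CapacityEstimate
from prepcost.ledger import CostCategory, ServiceModel
from prepcost.scenarios import CostReport
from prepcost.time_motion import DurationSummary, Role, StaffTimeProfile, VisitType

EM_DASH = "–"

CATEGORY_LABELS = {
    CostCategory.CAPITAL: "Capital",
    CostCategory.TRAINING: "Training",
    CostCategory.DEMAND_CREATION: "Demand creation",
    CostCategory.PERSONNEL_FIXED: "Personnel, fixed",
    CostCategory.OVERHEAD: "Overhead",
    CostCategory.ADMIN_SUPPLIES: "Admin (supplies), fixed",
    CostCategory.PERSONNEL_VARIABLE: "Personnel, variable",
    CostCategory.PREP_MEDICATION: "PrEP (supplies), variable",
    CostCategory.MISC_MEDICAL_SUPPLIES: "Miscellaneous medical supplies",
    CostCategory.HIV_TEST: "HIV serology test",
    CostCategory.HBSAG_TEST: "HBsAg test",
    CostCategory.CREATININE_TEST: "Creatinine test",
    CostCategory.PREGNANCY_TEST: "Pregnancy test",
    CostCategory.SYPHILIS_TEST: "Syphilis test",
}

TOTAL_ROW = "Total cost and cost per person month of PrEP"


def render_cost_table(reports: Sequence[CostReport]) -> pd.DataFrame:
    """Paired annual/unit cost columns for 1-9 (scenario, model) reports.

    Rows are the cost categories plus a total row; values are strings at
    two decimals, with an em-dash for categories excluded from a scenario.
    Duplicate (scenario, model) pairs are rejected.
    """
    if not 1 <= len(reports) <= 9:
        raise ValueError("expected between 1 and 9 cost reports")
    seen = set()
    for r in reports:
        key = (r.scenario_id, r.model)
        if key in seen:
            raise ValueError(f"duplicate report for {key[0].value}/{key[1].value}")
        seen.add(key)

    data: dict[str, list[str]] = {}
    index = [CATEGORY_LABELS[c] for c in CostCategory] + [TOTAL_ROW]
    for r in reports:
        stem = f"{r.scenario_id.value}/{r.model.value}"
        annual_col, unit_col = [], []
        for cat in CostCategory:
            if cat in r.categories:
                annual_col.append(f"{r.categories[cat]:.2f}")
                unit_col.append(f"{r.unit_costs[cat]:.2f}")
            else:
                annual_col.append(EM_DASH)
                unit_col.append(EM_DASH)
        annual_col.append(f"{r.total_annual:.2f}")
        unit_col.append(f"{r.cost_per_person_month:.2f}")
        data[f"{stem}:annual"] = annual_col
        data[f"{stem}:unit"] = unit_col
    return pd.DataFrame(data, index=index)


def parse_cost_table(csv_text: str) -> dict[str, dict[str, float | None]]:
    """Inverse of ``render_cost_table`` over CSV text (2-decimal precision).

    Returns ``{column: {row_label: value or None for excluded}}``.
    """
    frame = pd.read_csv(io.StringIO(csv_text), index_col=0)
    out: dict[str, dict[str, float | None]] = {}
    for col in frame.columns:
        out[col] = {
            row: (None if str(v).strip() == EM_DASH else float(v))
            for row, v in frame[col].items()
        }
    return out


def render_summary(
    summaries: Mapping[tuple[ServiceModel, VisitType], DurationSummary]
) -> str:
    """§-style duration report: one "median (IQR: lo, hi)" line per key."""
    if not summaries:
        raise ValueError("no duration summaries to render")
    lines = []
    for (model, vtype), s in sorted(
        summaries.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        lines.append(
            f"{model.value} {vtype.value}: {format_duration(s)} [n={s.n}]"
        )
    return "\n".join(lines)


def format_duration(s: DurationSummary) -> str:
    def fmt(x: float) -> str:
        return f"{x:.0f}" if float(x) == int(x) else f"{x:g}"

    return f"{fmt(s.median)} minutes (IQR: {fmt(s.iqr_low)}, {fmt(s.iqr_high)})"


def render_capacity(
    profile: StaffTimeProfile, estimates: Iterable[CapacityEstimate]
) -> pd.DataFrame:
    """Staff-time and throughput table per service model."""
    rows = {}
    visit_rows = (
        ("Initiation", VisitType.INITIATION),
        ("Monthly", VisitType.MONTHLY_REFILL),
        ("Quarterly", VisitType.QUARTERLY_REFILL),
    )
    for est in estimates:
        model = est.model
        col = {}
        for label, vt in visit_rows:
            for role in Role:
                mark = (
                    " (per group)" if profile.is_per_group(model, vt, role) else ""
                )
                col[f"{label} — {role.value}"] = (
                    f"{profile.get(model, vt, role):g}{mark}"
                )
        for role in Role:
            col[f"Total time — {role.value}"] = f"{profile.role_total(model, role):g}"
        col["Bottleneck cadre"] = est.bottleneck_role.value
        col["Clients per day"] = str(est.clients_per_day)
        if est.groups_per_day:
            col["Group sessions per day"] = ", ".join(
                f"{vt.value}: {g:.2f}" for vt, g in est.groups_per_day.items()
            )
        col["Annual person-months"] = str(est.annual_person_months)
        rows[model.value] = col
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunManifest:
    """Provenance stamp attached to every machine-readable output."""

    seed: int | None
    scenario_ids: tuple[str, ...]
    config_paths: tuple[str, ...] = ()
    software_version: str = ""
    timestamp: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scenario_ids": list(self.scenario_ids),
            "config_paths": list(self.config_paths),
            "software_version": self.software_version,
            "timestamp": self.timestamp,
            **self.extra,
        }
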
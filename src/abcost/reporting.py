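"""Rendering of breakdowns and comparisons to console and file formats.

Rendering never re-aggregates: every number shown is taken from the
breakdown the engine produced, formatted to two decimals.  Machine formats
(csv, json, markdown) always use dot decimals; the console table adds
thousands separators.
"""

from __future__ import annotations

import csv
import io
import json
from decimal import Decimal
from typing import Sequence

from pydantic import BaseModel, ConfigDict

from .cost_tables import to_cents
from .engine import (
    CostBreakdown,
    Perspective,
    _decimals_to_str,
    compare,
    get_perspective,
)

__all__ = ["ReportConfig", "render_breakdown", "render_comparison"]

OUTPUT_FORMATS = ("table-text", "csv", "json", "markdown")

#: display order and labels mirror the comparative-summary table shape
_ROW_ORDER = [
    ("prehospitalization", "Pre-hospitalization"),
    ("drugs", "Pharmacological therapy"),
    ("materials", "Materials"),
    ("personnel", "Healthcare professionals"),
    ("operating_room", "Operating room"),
    ("hospital_stay", "Hospital stay"),
]
_COURSE_LABELS = {
    "standard": "Standard post-operative course",
    "acute_complications": "Course with acute complications",
    "chronic_complications": "Course with chronic complications",
}


class ReportConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    perspective: Perspective = get_perspective("societal")
    mode: str = "fidelity"
    currency_label: str = "EUR"
    output_format: str = "table-text"
    include_audit: bool = False

    def __init__(self, **data):
        if isinstance(data.get("perspective"), str):
            data["perspective"] = get_perspective(data["perspective"])
        super().__init__(**data)
        if self.output_format not in OUTPUT_FORMATS:
            raise ValueError(
                f"output_format must be one of {OUTPUT_FORMATS}, "
                f"got {self.output_format!r}"
            )


def _fmt(value: Decimal, thousands: bool) -> str:
    q = to_cents(value)
    return f"{q:,.2f}" if thousands else f"{q:.2f}"


def _breakdown_rows(b: CostBreakdown) -> list[tuple[str, Decimal]]:
    rows = [(label, b.phase_costs[key]) for key, label in _ROW_ORDER
            if not (key == "operating_room" and b.phase_costs[key] == 0)]
    rows.append(("Subtotal for the procedure", b.procedure_subtotal))
    for course, value in b.followup_weighted.items():
        rows.append((_COURSE_LABELS.get(course, course), value))
    rows.append(("Subtotal for follow-up", b.followup_subtotal))
    if b.perspective.include_indirect:
        rows.append(("Productivity loss", b.phase_costs["productivity"]))
    rows.append(("Total intervention cost", b.grand_total))
    return rows


def render_breakdown(breakdown: CostBreakdown, config: ReportConfig) -> str:
    """One intervention's cost table in the configured output format."""
    rows = _breakdown_rows(breakdown)
    title = (f"{breakdown.intervention} "
             f"({breakdown.perspective.name}, {breakdown.mode} mode)")
    fmt = config.output_format
    if fmt == "json":
        return json.dumps(_decimals_to_str(breakdown.model_dump()), indent=2)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["category", f"cost_{config.currency_label.lower()}"])
        for label, value in rows:
            writer.writerow([label, _fmt(value, thousands=False)])
        return buf.getvalue()
    if fmt == "markdown":
        lines = [f"### {title}", "",
                 f"| Category | Cost ({config.currency_label}) |", "| --- | ---: |"]
        lines += [f"| {label} | {_fmt(v, thousands=False)} |" for label, v in rows]
        return "\n".join(lines) + "\n"
    # table-text
    width = max(len(label) for label, _ in rows)
    lines = [title, "-" * (width + 14)]
    for label, value in rows:
        lines.append(f"{label:<{width}}  {_fmt(value, thousands=True):>12}")
    if config.include_audit and breakdown.uplift_applied != 0:
        lines.append("")
        lines.append(f"retreatment uplift applied: x{1 + breakdown.uplift_applied}")
        for entry in breakdown.audit:
            lines.append(
                f"  {entry.component:<18} {_fmt(entry.pre_uplift, True):>12}"
                f" -> {_fmt(entry.post_uplift, True):>12}"
            )
    return "\n".join(lines) + "\n"


def render_comparison(
    breakdowns: Sequence[CostBreakdown], baseline: str, config: ReportConfig
) -> str:
    """Per-intervention totals plus savings relative to a baseline."""
    results = compare(breakdowns, baseline)
    by_name = {b.intervention: b for b in breakdowns}
    rows = []  # (name, total, absolute saving or None, relative saving or None)
    rows.append((baseline, by_name[baseline].grand_total, None, None))
    for res in results:
        rows.append((res.comparator, by_name[res.comparator].grand_total,
                     res.absolute_saving, res.relative_saving))

    def rel(r):
        return "" if r is None else f"{float(r) * 100:.1f}%"

    def absolute(a, thousands):
        return "" if a is None else _fmt(a, thousands)

    fmt = config.output_format
    if fmt == "json":
        payload = {
            "baseline": baseline,
            "perspective": breakdowns[0].perspective.name,
            "mode": breakdowns[0].mode,
            "interventions": [
                {"name": n, "grand_total": str(to_cents(t)),
                 "absolute_saving": None if a is None else str(to_cents(a)),
                 "relative_saving": None if r is None else float(r)}
                for n, t, a, r in rows
            ],
        }
        return json.dumps(payload, indent=2)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["intervention", "grand_total",
                         "absolute_saving_vs_baseline", "relative_saving"])
        for n, t, a, r in rows:
            writer.writerow([n, _fmt(t, False), absolute(a, False), rel(r)])
        return buf.getvalue()
    if fmt == "markdown":
        lines = [f"| Intervention | Total ({config.currency_label}) "
                 "| Saving vs baseline | Relative |", "| --- | ---: | ---: | ---: |"]
        lines += [f"| {n} | {_fmt(t, False)} | {absolute(a, False)} | {rel(r)} |"
                  for n, t, a, r in rows]
        return "\n".join(lines) + "\n"
    width = max(len(n) for n, *_ in rows)
    lines = [f"Comparison vs {baseline} "
             f"({breakdowns[0].perspective.name}, {breakdowns[0].mode} mode)",
             "-" * (width + 42)]
    for n, t, a, r in rows:
        lines.append(f"{n:<{width}}  {_fmt(t, True):>12}  "
                     f"{absolute(a, True):>12}  {rel(r):>7}")
    return "\n".join(lines) + "\n"
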
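"""Activity-based costing computations.

The engine turns an :class:`~abcost.cost_tables.InterventionDataset` into a
:class:`CostBreakdown`: per-phase costs, a retreatment uplift, an expected
follow-up cost over the complication mixture, a human-capital productivity
loss, and a grand total under a chosen accounting perspective.

Two computation modes are exposed:

``fidelity`` (default)
    Printed aggregates at the finest available level — phase totals from the
    per-treatment tables, follow-up course totals, printed patient
    productivity terms — are authoritative, and every component is rounded
    half-up to whole cents at its boundary.  This reproduces published
    summary tables to the cent wherever the source is internally consistent.

``raw``
    Everything is recomputed from quantities and unit costs with no
    intermediate rounding; printed aggregates are ignored (explicit
    ``phase_overrides`` still win — they are data, not metadata).  Raw-mode
    totals differ from fidelity totals only by the source's own rounding
    chains (well under 0.2% on the bundled datasets).

Perspectives:

``nhs_direct``
    direct payer costs only (no productivity loss).
``societal``
    direct costs plus patient/caregiver productivity loss.
``opportunity_cost_societal``
    societal minus the personnel phase: staff are salaried regardless of
    service delivery, so their time is an opportunity cost rather than a
    marginal outlay.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cost_tables import (
    CENT,
    RECONCILE_TOLERANCE,
    ComparisonError,
    ConfigurationError,
    CostItem,
    DatasetValidationError,
    DrugCategoryPolicy,
    DrugLine,
    FacilityParams,
    FollowUpCourse,
    IndirectCostParams,
    InterventionDataset,
    Money,
    PHASE_NAMES,
    ReconciliationNote,
    StaffLine,
    as_money,
    to_cents,
)

__all__ = [
    "Perspective",
    "PERSPECTIVES",
    "get_perspective",
    "ProductivityLoss",
    "AuditEntry",
    "CostBreakdown",
    "ComparisonResult",
    "item_cost",
    "phase_cost",
    "drug_category_costs",
    "drug_cost",
    "facility_cost",
    "staff_cost",
    "followup_expected_cost",
    "productivity_loss",
    "retreatment_uplift",
    "base_phase_costs",
    "intervention_total",
    "compare",
    "reconcile_summary",
    "breakdown_to_json",
    "breakdown_from_json",
]

#: phases scaled by (1 + retreatment rate); follow-up is excluded because a
#: repeat procedure re-enters the pathway before follow-up, and datasets that
#: need a follow-up adjustment carry it explicitly (residual or course items)
UPLIFTED_PHASES = (
    "prehospitalization",
    "drugs",
    "materials",
    "personnel",
    "operating_room",
    "hospital_stay",
    "productivity",
)


class Perspective(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    include_indirect: bool
    exclude_personnel: bool

    @model_validator(mode="after")
    def _consistent(self):
        known = {
            "nhs_direct": (False, False),
            "societal": (True, False),
            "opportunity_cost_societal": (True, True),
        }
        if self.name in known and known[self.name] != (
            self.include_indirect, self.exclude_personnel
        ):
            raise ValueError(f"flags inconsistent with perspective {self.name!r}")
        return self


PERSPECTIVES = {
    "nhs_direct": Perspective(
        name="nhs_direct", include_indirect=False, exclude_personnel=False),
    "societal": Perspective(
        name="societal", include_indirect=True, exclude_personnel=False),
    "opportunity_cost_societal": Perspective(
        name="opportunity_cost_societal", include_indirect=True,
        exclude_personnel=True),
}


def get_perspective(which) -> Perspective:
    if isinstance(which, Perspective):
        return which
    try:
        return PERSPECTIVES[which]
    except KeyError:
        raise ConfigurationError(
            f"unknown perspective {which!r}; choose from {sorted(PERSPECTIVES)}"
        ) from None


class ProductivityLoss(BaseModel):
    """Indirect cost of one intervention (human-capital approach)."""

    model_config = ConfigDict(frozen=True)

    patient_loss: Decimal
    caregiver_loss: Decimal
    total_loss: Decimal
    total_days: Decimal


class AuditEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    component: str
    pre_uplift: Decimal
    post_uplift: Decimal


class CostBreakdown(BaseModel):
    """Computed costs of one intervention under one perspective and mode."""

    model_config = ConfigDict(frozen=True)

    intervention: str
    perspective: Perspective
    mode: str
    uplift_applied: Decimal
    phase_costs: dict[str, Decimal]
    followup_weighted: dict[str, Decimal] = Field(default_factory=dict)
    procedure_subtotal: Decimal
    followup_subtotal: Decimal
    grand_total: Decimal
    audit: list[AuditEntry]


class ComparisonResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    baseline: str
    comparator: str
    absolute_saving: Decimal
    relative_saving: Decimal


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def item_cost(item: CostItem) -> Money:
    """Per-patient cost of one driver line.

    The weighted per-patient override wins when present; otherwise
    quantity x unit cost; a flat item (no quantity) costs its unit_cost.
    """
    if item.weighted_cost_override is not None:
        return item.weighted_cost_override
    if item.quantity is None:
        return item.unit_cost
    return item.quantity * item.unit_cost


def phase_cost(items: Sequence[CostItem], override: Optional[Money] = None) -> Money:
    """Sum of item costs; an explicit override wins; empty phase costs 0."""
    if override is not None:
        return as_money(override)
    return sum((item_cost(i) for i in items), Decimal(0))


def drug_category_costs(
    lines: Sequence[DrugLine], policies: Sequence[DrugCategoryPolicy]
) -> dict[str, Money]:
    """Unrounded per-category cost under each category's aggregation policy.

    ``mean_of_alternatives`` averages the line costs (alternative agents used
    with equal likelihood), ``sum_of_lines`` adds them (co-administration),
    ``printed_override`` uses the pinned value.  The ``other`` category is
    always co-administered and therefore always sums.
    """
    by_policy = {p.category: p for p in policies}
    out: dict[str, Money] = {}
    for line in lines:
        if line.category not in by_policy and line.category != "other":
            raise ConfigurationError(
                f"drug line {line.drug!r}: no policy for category {line.category!r}"
            )
        out.setdefault(line.category, Decimal(0))
    for category in out:
        costs = [l.cost for l in lines if l.category == category]
        policy = by_policy.get(category)
        if category == "other" or (policy and policy.aggregation == "sum_of_lines"):
            out[category] = sum(costs, Decimal(0))
        elif policy.aggregation == "printed_override":
            out[category] = policy.override_cost
        else:  # mean_of_alternatives
            out[category] = sum(costs, Decimal(0)) / len(costs)
    return out


def drug_cost(
    lines: Sequence[DrugLine], policies: Sequence[DrugCategoryPolicy]
) -> Money:
    """Total pharmacological cost: sum of unrounded category costs.

    Category costs are summed before any rounding; published totals were
    computed that way (rounding the displayed category values first can be a
    cent off).
    """
    return sum(drug_category_costs(lines, policies).values(), Decimal(0))


def facility_cost(params: FacilityParams, mode: str = "fidelity") -> tuple[Money, Money]:
    """(operating-room cost, hospital-stay cost).

    Fidelity mode prefers the printed costs and falls back to
    duration x rate; raw mode prefers duration x rate (so parameter sweeps
    on durations take effect) and falls back to the printed cost.
    """
    _check_mode(mode)

    def one(duration, rate, printed, what) -> Money:
        if rate is not None and duration is None:
            raise ConfigurationError(f"{what}: rate given without a duration")
        from_rate = duration * rate if (duration is not None and rate is not None) else None
        if mode == "fidelity":
            chosen = printed if printed is not None else from_rate
        else:
            chosen = from_rate if from_rate is not None else printed
        return chosen if chosen is not None else Decimal(0)

    or_cost = one(params.or_minutes, params.or_rate_per_minute, params.or_cost,
                  "operating room")
    stay_cost = one(params.stay_days, params.stay_rate_per_day, params.stay_cost,
                    "hospital stay")
    if params.stay_days == 0 and params.stay_cost is None:
        stay_cost = Decimal(0)
    return or_cost, stay_cost


def staff_cost(lines: Sequence[StaffLine]) -> Money:
    """Total personnel cost (line costs already reflect engagement time)."""
    return sum((l.cost for l in lines), Decimal(0))


def followup_expected_cost(
    courses: Sequence[FollowUpCourse],
    residual: Money = Decimal(0),
    mode: str = "fidelity",
) -> Money:
    """Frequency-weighted expected annual follow-up cost.

    Each course contributes frequency x annual cost; frequencies may sum to
    less than 1 (the remainder has no follow-up cost).  ``residual`` is a
    flat addition carried by the dataset.  Fidelity mode costs a course at
    its printed total when available; raw mode recomputes from items.
    """
    _check_mode(mode)
    fsum = sum((c.frequency for c in courses), Decimal(0))
    if fsum > 1 + CENT / 100:
        raise DatasetValidationError(
            f"follow-up course frequencies must sum to <= 1, got {fsum}"
        )
    total = as_money(residual)
    for course in courses:
        if mode == "fidelity" and course.printed_total is not None:
            cost = course.printed_total
        elif course.items:
            cost = phase_cost(course.items)
        else:
            cost = course.printed_total if course.printed_total is not None else Decimal(0)
        total += course.frequency * cost
    return total


def productivity_loss(params: IndirectCostParams, mode: str = "fidelity") -> ProductivityLoss:
    """Human-capital productivity loss of patient and caregiver.

    patient = (hospitalization + convalescence days) x hours lost/day x wage;
    caregiver = caregiver share x patient; total = patient + caregiver.
    In fidelity mode a printed patient term (which may embed an
    employment-category weighting) replaces the raw product, and terms are
    rounded to cents.
    """
    _check_mode(mode)
    days = params.hosp_days + params.convalescence_days
    patient = days * params.hours_lost_per_day * params.hourly_wage
    if mode == "fidelity":
        if params.printed_patient_loss is not None:
            patient = params.printed_patient_loss
        patient = to_cents(patient)
        caregiver = to_cents(params.caregiver_share * patient)
    else:
        caregiver = params.caregiver_share * patient
    return ProductivityLoss(
        patient_loss=patient,
        caregiver_loss=caregiver,
        total_loss=patient + caregiver,
        total_days=days,
    )


def retreatment_uplift(value: Money, rate: Money, quantize: bool = True) -> Money:
    """Scale a per-patient cost by (1 + retreatment rate)."""
    rate = as_money(rate)
    if rate < 0:
        raise DatasetValidationError(f"retreatment rate must be >= 0, got {rate}")
    out = as_money(value) * (1 + rate)
    return to_cents(out) if quantize else out


# ---------------------------------------------------------------------------
# Whole-intervention totals
# ---------------------------------------------------------------------------

def _check_mode(mode: str):
    if mode not in ("fidelity", "raw"):
        raise ConfigurationError(f"mode must be 'fidelity' or 'raw', got {mode!r}")


def base_phase_costs(dataset: InterventionDataset, mode: str = "fidelity") -> dict[str, Money]:
    """Pre-uplift cost of every phase.

    Resolution order per phase: an explicit ``phase_overrides`` entry always
    wins (both modes); in fidelity mode a ``printed_phase_totals`` entry is
    honored next; otherwise the phase is recomputed from its rows.  Fidelity
    rounds each phase to cents at its boundary; raw keeps full precision.
    """
    _check_mode(mode)
    or_cost, stay_cost = facility_cost(dataset.facility, mode=mode)
    computed: dict[str, Money] = {
        "prehospitalization": phase_cost(dataset.prehosp_items),
        "drugs": drug_cost(dataset.drug_lines, dataset.drug_policies),
        "materials": phase_cost(dataset.material_items),
        "personnel": staff_cost(dataset.staff_lines),
        "operating_room": or_cost,
        "hospital_stay": stay_cost,
        "followup": followup_expected_cost(
            dataset.followup_courses, dataset.followup_residual, mode=mode),
        "productivity": productivity_loss(dataset.indirect, mode=mode).total_loss,
    }
    out: dict[str, Money] = {}
    for phase in PHASE_NAMES:
        if phase in dataset.phase_overrides:
            # overrides are data pinned at their stated precision (possibly
            # sub-cent, e.g. an inferred pre-uplift base); never re-rounded
            out[phase] = dataset.phase_overrides[phase]
            continue
        if mode == "fidelity" and phase in dataset.printed_phase_totals:
            value = dataset.printed_phase_totals[phase]
        else:
            value = computed[phase]
        out[phase] = to_cents(value) if mode == "fidelity" else value
    return out


def intervention_total(
    dataset: InterventionDataset,
    perspective="societal",
    mode: str = "fidelity",
) -> CostBreakdown:
    """Full per-patient cost of one intervention.

    Applies the retreatment uplift to every phase except follow-up, selects
    phases according to the perspective, and returns a breakdown whose grand
    total is the exact sum of its own audit components.
    """
    _check_mode(mode)
    persp = get_perspective(perspective)
    rate = dataset.retreatment_rate
    base = base_phase_costs(dataset, mode=mode)

    post: dict[str, Money] = {}
    audit: list[AuditEntry] = []
    for phase in PHASE_NAMES:
        if phase in UPLIFTED_PHASES and rate != 0:
            post[phase] = retreatment_uplift(base[phase], rate,
                                             quantize=(mode == "fidelity"))
        else:
            post[phase] = base[phase]
        audit.append(AuditEntry(component=phase, pre_uplift=base[phase],
                                post_uplift=post[phase]))

    procedure = (post["drugs"] + post["materials"] + post["personnel"]
                 + post["operating_room"] + post["hospital_stay"])
    followup = post["followup"]
    grand = post["prehospitalization"] + procedure + followup
    if persp.include_indirect:
        grand += post["productivity"]
    if persp.exclude_personnel:
        grand -= post["personnel"]

    weighted: dict[str, Money] = {}
    for course in dataset.followup_courses:
        if mode == "fidelity" and course.printed_total is not None:
            cost = course.printed_total
        else:
            cost = phase_cost(course.items) if course.items else (
                course.printed_total or Decimal(0))
        w = course.frequency * cost
        weighted[course.name] = to_cents(w) if mode == "fidelity" else w

    return CostBreakdown(
        intervention=dataset.name,
        perspective=persp,
        mode=mode,
        uplift_applied=rate,
        phase_costs=post,
        followup_weighted=weighted,
        procedure_subtotal=procedure,
        followup_subtotal=followup,
        grand_total=grand,
        audit=audit,
    )


def compare(
    breakdowns: Sequence[CostBreakdown], baseline: str
) -> list[ComparisonResult]:
    """Absolute and relative savings of each intervention vs a baseline.

    relative saving = 1 - comparator total / baseline total.  All breakdowns
    must share a perspective and mode.
    """
    if len(breakdowns) < 2:
        raise ComparisonError("need at least two breakdowns to compare")
    names = {b.perspective.name for b in breakdowns}
    modes = {b.mode for b in breakdowns}
    if len(names) > 1 or len(modes) > 1:
        raise ComparisonError(
            f"mixed perspectives {sorted(names)} or modes {sorted(modes)}"
        )
    by_name = {b.intervention: b for b in breakdowns}
    if baseline not in by_name:
        raise ComparisonError(f"baseline {baseline!r} not among breakdowns")
    base_total = by_name[baseline].grand_total
    out = []
    for b in breakdowns:
        if b.intervention == baseline:
            continue
        absolute = base_total - b.grand_total
        relative = (1 - b.grand_total / base_total) if base_total != 0 else Decimal(0)
        out.append(ComparisonResult(
            baseline=baseline, comparator=b.intervention,
            absolute_saving=absolute, relative_saving=relative,
        ))
    return out


# ---------------------------------------------------------------------------
# Summary-level reconciliation (printed comparative-table values)
# ---------------------------------------------------------------------------

#: summary_reference keys -> how to compute the engine-side value
_SUMMARY_PHASE_KEYS = {
    "prehospitalization": "prehospitalization",
    "drugs": "drugs",
    "materials": "materials",
    "personnel": "personnel",
    "operating_room": "operating_room",
    "hospital_stay": "hospital_stay",
    "productivity": "productivity",
}


def reconcile_summary(dataset: InterventionDataset) -> list[ReconciliationNote]:
    """Check published summary-table values against fidelity-mode results.

    Compares the post-uplift phase rows, the procedure and follow-up
    subtotals, the weighted course rows, per-perspective grand totals, and
    any raw per-treatment materials-table total (items plus facility).
    Entries beyond the tolerance come back as mismatches — this is how the
    source's documented errata surface.
    """
    from .cost_tables import _note  # shared note constructor

    ref = dataset.summary_reference
    if not ref:
        return []
    notes: list[ReconciliationNote] = []
    societal = intervention_total(dataset, "societal", mode="fidelity")
    post = societal.phase_costs
    for key, phase in _SUMMARY_PHASE_KEYS.items():
        if key in ref:
            notes.append(_note(f"{dataset.name}: summary {key}", ref[key], post[phase]))
    if "procedure_subtotal" in ref:
        notes.append(_note(f"{dataset.name}: summary procedure subtotal",
                           ref["procedure_subtotal"], societal.procedure_subtotal))
    if "followup_subtotal" in ref:
        notes.append(_note(f"{dataset.name}: summary followup subtotal",
                           ref["followup_subtotal"], societal.followup_subtotal))
    for course, value in societal.followup_weighted.items():
        key = f"followup_weighted.{course}"
        if key in ref:
            notes.append(_note(f"{dataset.name}: summary {key}", ref[key], value))
    for pname in PERSPECTIVES:
        key = f"grand_total.{pname}"
        if key in ref:
            total = intervention_total(dataset, pname, mode="fidelity").grand_total
            notes.append(_note(f"{dataset.name}: summary grand total ({pname})",
                               ref[key], total))
    if "materials_table_total" in ref:
        or_cost, stay_cost = facility_cost(dataset.facility, mode="fidelity")
        table_sum = phase_cost(dataset.material_items) + or_cost + stay_cost
        notes.append(_note(f"{dataset.name}: materials table total",
                           ref["materials_table_total"], table_sum))
    return notes


# ---------------------------------------------------------------------------
# JSON round-trip of breakdowns
# ---------------------------------------------------------------------------

def _decimals_to_str(obj):
    if isinstance(obj, Decimal):
        return format(obj, "f")
    if isinstance(obj, dict):
        return {k: _decimals_to_str(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decimals_to_str(v) for v in obj]
    return obj


def breakdown_to_json(breakdown: CostBreakdown) -> str:
    import json

    return json.dumps(_decimals_to_str(breakdown.model_dump()), indent=2)


def breakdown_from_json(payload: str) -> CostBreakdown:
    import json

    return CostBreakdown.model_validate(json.loads(payload))
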
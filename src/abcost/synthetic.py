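"""Random intervention datasets with known analytic totals.

The generator emits datasets with the structure the costing model assumes —
phase-partitioned item lists with non-negative quantities and prices, drug
categories with aggregation policies, facility durations with per-unit
rates, follow-up course frequencies summing to at most one, indirect-cost
parameters, and an optional retreatment rate — together with ground-truth
grand totals under all three perspectives.

The truth is computed inside the generator by a straight-line walk over the
rows (literal loops, no calls into the engine), so it serves as an
independent oracle for the engine's aggregation: on any bundle,
``intervention_total(bundle.dataset, p).grand_total`` must equal
``bundle.truth[p]`` to the cent.

All sampling is from bounded distributions on exact two-decimal (money) or
four-decimal (rates, fractions) grids, keeping every assertion exact in
cents.  What the generator does NOT emulate: printed-aggregate metadata and
its rounding drift (synthetic datasets are internally consistent by
construction), patient-level heterogeneity, and multi-year follow-up.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cost_tables import (
    CostItem,
    DatasetValidationError,
    DrugCategoryPolicy,
    DrugLine,
    FacilityParams,
    FollowUpCourse,
    IndirectCostParams,
    InterventionDataset,
    StaffLine,
)

__all__ = ["SynthConfig", "SynthBundle", "generate_dataset", "generate_paperlike"]

_CENT = Decimal("0.01")

_CATEGORIES = ("anesthetics", "opioids", "antibiotics", "corticosteroids", "other")
_COURSES = ("standard", "acute_complications", "chronic_complications")
_ROLES = ("Physician", "Nurse", "Anesthetist", "Healthcare assistant",
          "Surgical instrument technician")


class SynthConfig(BaseModel):
    """Sampling ranges for one synthetic dataset; the seed is mandatory."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_items_per_phase: tuple[int, int] = (3, 14)
    price_range: tuple[float, float] = (0.5, 500.0)
    quantity_range: tuple[float, float] = (0.0, 10.0)
    course_count: int = 3
    frequency_concentration: float = 5.0
    retreatment_rate_range: tuple[float, float] = (0.0, 0.3)
    caregiver_share_range: tuple[float, float] = (0.0, 0.2)

    @model_validator(mode="after")
    def _check(self):
        errors = []
        if self.n_items_per_phase[0] < 0 or self.n_items_per_phase[0] > self.n_items_per_phase[1]:
            errors.append("n_items_per_phase must be a non-empty range of counts")
        for name, (lo, hi), bound in (
            ("price_range", self.price_range, None),
            ("quantity_range", self.quantity_range, None),
            ("retreatment_rate_range", self.retreatment_rate_range, Decimal("0.5")),
            ("caregiver_share_range", self.caregiver_share_range, Decimal(1)),
        ):
            if lo < 0 or lo > hi:
                errors.append(f"{name} must satisfy 0 <= low <= high")
            if bound is not None and Decimal(repr(hi)) > bound:
                errors.append(f"{name} upper bound exceeds {bound}")
        if not (1 <= self.course_count <= 3):
            errors.append("course_count must be 1..3")
        if self.frequency_concentration <= 0:
            errors.append("frequency_concentration must be positive")
        if errors:
            raise DatasetValidationError(errors)
        return self


class SynthBundle(BaseModel):
    model_config = ConfigDict(frozen=True)

    dataset: InterventionDataset
    #: perspective name -> analytic grand total, computed by the generator's
    #: own accumulation (the oracle), not by the engine
    truth: dict[str, Decimal]


# ---------------------------------------------------------------------------
# sampling helpers: everything lands on an exact decimal grid
# ---------------------------------------------------------------------------

def _grid(rng: np.random.Generator, lo: float, hi: float, places: int) -> Decimal:
    scale = 10 ** places
    lo_i, hi_i = int(round(lo * scale)), int(round(hi * scale))
    return Decimal(int(rng.integers(lo_i, hi_i + 1))) / scale


def _money(rng, lo, hi) -> Decimal:
    return _grid(rng, lo, hi, 2)


def _item(rng: np.random.Generator, cfg: SynthConfig, label: str) -> CostItem:
    kind = rng.integers(0, 3)
    price = _money(rng, *cfg.price_range)
    if kind == 0:  # flat cost, no quantity
        return CostItem(label=label, unit_cost=price)
    qty = _grid(rng, *cfg.quantity_range, 2)
    if kind == 1:  # quantity x unit price
        return CostItem(label=label, quantity=qty, unit_cost=price)
    return CostItem(label=label, quantity=qty, weighted_cost_override=price)


def _items(rng, cfg, prefix: str) -> list[CostItem]:
    n = int(rng.integers(cfg.n_items_per_phase[0], cfg.n_items_per_phase[1] + 1))
    return [_item(rng, cfg, f"{prefix} {i + 1}") for i in range(n)]


def _frequencies(rng: np.random.Generator, cfg: SynthConfig) -> list[Decimal]:
    """Course frequencies on a 4-decimal grid, summing to at most 1.

    Raw gamma weights are scaled by a factor that sometimes leaves a
    residual no-follow-up fraction and sometimes overshoots; overshoot is
    renormalized to exactly 1.  Rounding down keeps the sum bound exact.
    """
    w = rng.gamma(cfg.frequency_concentration, 1.0, size=cfg.course_count)
    scale = rng.uniform(0.6, 1.1)
    f = w / w.sum() * min(scale, 1.0)
    out = [Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_DOWN)
           for x in f]
    return out


def generate_dataset(config: SynthConfig) -> SynthBundle:
    """Generate one dataset plus its analytic ground truth.

    Deterministic in the seed: the same config yields the identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config

    prehosp = _items(rng, cfg, "Work-up")
    materials = _items(rng, cfg, "Material")

    drug_lines: list[DrugLine] = []
    policies: list[DrugCategoryPolicy] = []
    for category in _CATEGORIES:
        if rng.random() < 0.3 and category != "other":
            continue
        n_lines = int(rng.integers(1, 4))
        for j in range(n_lines):
            drug_lines.append(DrugLine(
                category=category, drug=f"{category} drug {j + 1}",
                dose_mg=_grid(rng, 0, 1000, 2),
                cost=_money(rng, *cfg.price_range),
            ))
        if category == "other":
            policies.append(DrugCategoryPolicy(category=category,
                                               aggregation="sum_of_lines"))
        else:
            choice = rng.integers(0, 3)
            if choice == 0:
                policies.append(DrugCategoryPolicy(
                    category=category, aggregation="printed_override",
                    override_cost=_money(rng, *cfg.price_range)))
            else:
                policies.append(DrugCategoryPolicy(
                    category=category,
                    aggregation="mean_of_alternatives" if choice == 1
                    else "sum_of_lines"))

    staff = [
        StaffLine(role=role, headcount=_grid(rng, 0.5, 3, 2),
                  cost=_money(rng, *cfg.price_range))
        for role in _ROLES[: int(rng.integers(2, 6))]
    ]

    stay_days = _grid(rng, 0, 5, 2)
    stay_rate = _money(rng, *cfg.price_range)
    facility_kwargs = {"stay_days": stay_days, "stay_rate_per_day": stay_rate}
    if rng.random() < 0.5:  # sometimes the cost is printed, sometimes derived
        facility_kwargs["stay_cost"] = (stay_days * stay_rate).quantize(
            _CENT, rounding=ROUND_HALF_UP)
    if rng.random() < 0.6:
        or_minutes = _grid(rng, 10, 180, 2)
        or_rate = _grid(rng, *cfg.price_range, 4)
        facility_kwargs.update(
            or_minutes=or_minutes, or_rate_per_minute=or_rate,
            or_cost=(or_minutes * or_rate).quantize(_CENT, rounding=ROUND_HALF_UP),
        )
    facility = FacilityParams(**facility_kwargs)

    freqs = _frequencies(rng, cfg)
    courses = [
        FollowUpCourse(name=_COURSES[i], frequency=freqs[i],
                       items=_items(rng, cfg, f"Follow-up {i + 1}"))
        for i in range(cfg.course_count)
    ]

    indirect = IndirectCostParams(
        hosp_days=stay_days,
        convalescence_days=_grid(rng, 0, 30, 2),
        hours_lost_per_day=_grid(rng, 4, 8, 1),
        hourly_wage=_money(rng, *cfg.price_range),
        caregiver_share=_grid(rng, *cfg.caregiver_share_range, 4),
    )

    overrides: dict[str, Decimal] = {}
    if rng.random() < 0.2:  # exercise the override path
        overrides["materials"] = _money(rng, *cfg.price_range)

    dataset = InterventionDataset(
        name=f"synthetic-{cfg.seed}",
        prehosp_items=prehosp,
        drug_lines=drug_lines,
        drug_policies=policies,
        material_items=materials,
        staff_lines=staff,
        facility=facility,
        followup_courses=courses,
        indirect=indirect,
        retreatment_rate=_grid(rng, *cfg.retreatment_rate_range, 4),
        phase_overrides=overrides,
    )
    return SynthBundle(dataset=dataset, truth=_closed_form_truth(dataset))


def generate_paperlike(seed: int = 0) -> SynthBundle:
    """A dataset with the bundled studies' exact shape but randomized values.

    14 work-up items, five drug categories with one pinned category cost,
    five staff roles, operating room plus stay, three follow-up courses at
    frequencies 0.93 / 0.035 / 0.035, and a 15% retreatment rate.  Used to
    stress-test fidelity/raw agreement on realistically shaped data.
    """
    rng = np.random.default_rng(seed)
    cfg = SynthConfig(seed=seed, n_items_per_phase=(14, 14),
                      price_range=(0.5, 120.0), quantity_range=(0.0, 10.0))

    prehosp = _items(rng, cfg, "Work-up")
    materials = _items(rng, cfg, "Material")
    drug_lines, policies = [], []
    for category, n_lines in zip(_CATEGORIES, (3, 2, 2, 2, 2)):
        for j in range(n_lines):
            drug_lines.append(DrugLine(
                category=category, drug=f"{category} drug {j + 1}",
                dose_mg=_grid(rng, 0, 1000, 2), cost=_money(rng, 0, 12)))
        if category == "anesthetics":
            policies.append(DrugCategoryPolicy(
                category=category, aggregation="printed_override",
                override_cost=_money(rng, 0, 5)))
        elif category == "other":
            policies.append(DrugCategoryPolicy(category=category,
                                               aggregation="sum_of_lines"))
        else:
            policies.append(DrugCategoryPolicy(
                category=category, aggregation="mean_of_alternatives"))
    staff = [StaffLine(role=role, headcount=_grid(rng, 0.5, 2.5, 2),
                       cost=_money(rng, 15, 100)) for role in _ROLES]
    stay_days = _grid(rng, 1, 3, 2)
    stay_rate = _money(rng, 400, 900)
    or_minutes = _grid(rng, 30, 120, 2)
    or_rate = _grid(rng, 10, 30, 4)
    facility = FacilityParams(
        stay_days=stay_days, stay_rate_per_day=stay_rate,
        stay_cost=(stay_days * stay_rate).quantize(_CENT, rounding=ROUND_HALF_UP),
        or_minutes=or_minutes, or_rate_per_minute=or_rate,
        or_cost=(or_minutes * or_rate).quantize(_CENT, rounding=ROUND_HALF_UP),
    )
    courses = [
        FollowUpCourse(name=name, frequency=freq,
                       items=[_item(rng, cfg, f"{name} item {i + 1}")
                              for i in range(8)])
        for name, freq in zip(_COURSES,
                              (Decimal("0.93"), Decimal("0.035"), Decimal("0.035")))
    ]
    indirect = IndirectCostParams(
        hosp_days=stay_days, convalescence_days=_grid(rng, 5, 15, 2),
        hours_lost_per_day=Decimal(5), hourly_wage=Decimal("14.05"),
        caregiver_share=_grid(rng, 0.02, 0.10, 4),
    )
    dataset = InterventionDataset(
        name=f"paperlike-{seed}",
        prehosp_items=prehosp, drug_lines=drug_lines, drug_policies=policies,
        material_items=materials, staff_lines=staff, facility=facility,
        followup_courses=courses, indirect=indirect,
        retreatment_rate=Decimal("0.15"),
    )
    return SynthBundle(dataset=dataset, truth=_closed_form_truth(dataset))


# ---------------------------------------------------------------------------
# Independent ground truth: a straight-line accumulation over the rows.
# Deliberately does NOT import the engine; the duplication is the point.
# ---------------------------------------------------------------------------

def _cents(x: Decimal) -> Decimal:
    return x.quantize(_CENT, rounding=ROUND_HALF_UP)


def _truth_item(item: CostItem) -> Decimal:
    if item.weighted_cost_override is not None:
        return item.weighted_cost_override
    if item.quantity is None:
        return item.unit_cost
    return item.quantity * item.unit_cost


def _closed_form_truth(d: InterventionDataset) -> dict[str, Decimal]:
    prehosp = Decimal(0)
    for item in d.prehosp_items:
        prehosp += _truth_item(item)

    drugs = Decimal(0)
    policy_by_cat = {p.category: p for p in d.drug_policies}
    for category in {l.category for l in d.drug_lines}:
        costs = [l.cost for l in d.drug_lines if l.category == category]
        policy = policy_by_cat.get(category)
        if category == "other" or (policy and policy.aggregation == "sum_of_lines"):
            cat_cost = Decimal(0)
            for c in costs:
                cat_cost += c
        elif policy.aggregation == "printed_override":
            cat_cost = policy.override_cost
        else:
            total = Decimal(0)
            for c in costs:
                total += c
            cat_cost = total / len(costs)
        drugs += cat_cost

    materials = Decimal(0)
    for item in d.material_items:
        materials += _truth_item(item)
    if "materials" in d.phase_overrides:
        materials = d.phase_overrides["materials"]

    personnel = Decimal(0)
    for line in d.staff_lines:
        personnel += line.cost

    fac = d.facility
    if fac.or_cost is not None:
        or_cost = fac.or_cost
    elif fac.or_minutes is not None and fac.or_rate_per_minute is not None:
        or_cost = fac.or_minutes * fac.or_rate_per_minute
    else:
        or_cost = Decimal(0)
    if fac.stay_cost is not None:
        stay_cost = fac.stay_cost
    elif fac.stay_rate_per_day is not None:
        stay_cost = fac.stay_days * fac.stay_rate_per_day
    else:
        stay_cost = Decimal(0)

    followup = d.followup_residual
    for course in d.followup_courses:
        course_cost = Decimal(0)
        for item in course.items:
            course_cost += _truth_item(item)
        if not course.items and course.printed_total is not None:
            course_cost = course.printed_total
        followup += course.frequency * course_cost

    ind = d.indirect
    patient = _cents((ind.hosp_days + ind.convalescence_days)
                     * ind.hours_lost_per_day * ind.hourly_wage)
    caregiver = _cents(ind.caregiver_share * patient)
    productivity = patient + caregiver

    r = d.retreatment_rate
    phases = {
        "prehospitalization": prehosp, "drugs": drugs, "materials": materials,
        "personnel": personnel, "operating_room": or_cost,
        "hospital_stay": stay_cost, "productivity": productivity,
    }
    uplifted = {k: _cents(_cents(v) * (1 + r)) for k, v in phases.items()}
    uplifted["followup"] = _cents(followup)

    direct = (uplifted["prehospitalization"] + uplifted["drugs"]
              + uplifted["materials"] + uplifted["personnel"]
              + uplifted["operating_room"] + uplifted["hospital_stay"]
              + uplifted["followup"])
    societal = direct + uplifted["productivity"]
    return {
        "nhs_direct": direct,
        "societal": societal,
        "opportunity_cost_societal": societal - uplifted["personnel"],
    }
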
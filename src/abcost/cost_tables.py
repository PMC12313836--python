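"""Intervention cost datasets: domain types, file formats, bundled fixtures.

An :class:`InterventionDataset` is a declarative description of every cost
driver of one treatment pathway, organised the way hospital micro-costing
studies report them: pre-hospitalization work-up items, drug lines grouped by
category, consumable materials, staff involvement, facility use (operating
room minutes and bed-days), post-operative follow-up courses with population
frequencies, and the indirect-cost (productivity-loss) parameters.

All money is carried as :class:`decimal.Decimal` (EUR); display rounding is
half-up to two decimals and happens only at component boundaries or at
rendering time.  Published tables frequently carry one-cent rounding drift,
so printed aggregates are stored alongside the raw rows and checked against
recomputed sums with a tolerance of 0.02 EUR per aggregation step by
:func:`reconcile` — mismatches beyond the tolerance are reported, never
silently corrected.

Two on-disk dialects are supported: a single YAML document (top-level keys
mirror the dataset fields) and a CSV bundle (a directory of UTF-8 CSV files
with dot decimal separators).  ``write_dataset`` followed by ``load_dataset``
is the identity, field for field.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Money",
    "CENT",
    "RECONCILE_TOLERANCE",
    "to_cents",
    "as_money",
    "CostItem",
    "DrugLine",
    "DrugCategoryPolicy",
    "StaffLine",
    "FacilityParams",
    "FollowUpCourse",
    "IndirectCostParams",
    "InterventionDataset",
    "ReconciliationNote",
    "reconcile",
    "load_dataset",
    "write_dataset",
    "bundled_dataset",
    "bundled_datasets",
    "BUNDLED_NAMES",
    "DatasetFormatError",
    "DatasetValidationError",
    "ConfigurationError",
    "ComparisonError",
]

Money = Decimal
CENT = Decimal("0.01")
#: allowed drift between a recomputed aggregate and a printed one, per step
RECONCILE_TOLERANCE = Decimal("0.02")

DRUG_CATEGORIES = ("anesthetics", "opioids", "antibiotics", "corticosteroids", "other")
COURSE_NAMES = ("standard", "acute_complications", "chronic_complications")
PHASE_NAMES = (
    "prehospitalization",
    "drugs",
    "materials",
    "personnel",
    "operating_room",
    "hospital_stay",
    "followup",
    "productivity",
)


class DatasetFormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class DatasetValidationError(ValueError):
    """One or more dataset invariants are violated.

    ``errors`` lists every violation at once so a file can be fixed in a
    single pass.
    """

    def __init__(self, errors: list[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = errors
        super().__init__("; ".join(errors))


class ConfigurationError(ValueError):
    """An operation was invoked with an inconsistent configuration."""


class ComparisonError(ValueError):
    """Breakdowns computed under different perspectives/modes were mixed."""


def as_money(value) -> Decimal:
    """Convert a number to Decimal without binary-float contamination."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, (int, str)):
        return Decimal(value)
    if isinstance(value, float):
        # repr() gives the shortest decimal string that round-trips
        return Decimal(repr(value))
    raise TypeError(f"cannot interpret {value!r} as money")


def to_cents(value: Decimal) -> Decimal:
    """Round half-up to whole cents."""
    return as_money(value).quantize(CENT, rounding=ROUND_HALF_UP)


def _non_negative(name: str, v: Optional[Decimal]) -> Optional[Decimal]:
    if v is not None and v < 0:
        raise ValueError(f"{name} must be >= 0, got {v}")
    return v


class _Base(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


class CostItem(_Base):
    """One cost-driver line of a phase table.

    ``quantity`` is the mean number of units consumed per patient and may be
    fractional or absent; an absent quantity marks a flat per-patient cost
    (tables print such rows with "N/A").  ``weighted_cost_override`` is used
    when the source table prints an already-weighted per-patient cost instead
    of a unit price; when present it is authoritative for costing and
    ``unit_cost``/``quantity`` remain as documentation.
    """

    label: str
    quantity: Optional[Decimal] = None
    unit_cost: Optional[Decimal] = None
    weighted_cost_override: Optional[Decimal] = None

    @field_validator("quantity", "unit_cost", "weighted_cost_override", mode="before")
    @classmethod
    def _coerce(cls, v):
        return None if v is None else as_money(v)

    @model_validator(mode="after")
    def _check(self):
        _non_negative("quantity", self.quantity)
        _non_negative("unit_cost", self.unit_cost)
        _non_negative("weighted_cost_override", self.weighted_cost_override)
        if self.unit_cost is None and self.weighted_cost_override is None:
            raise ValueError(
                f"item {self.label!r}: needs unit_cost or weighted_cost_override"
            )
        return self


class DrugLine(_Base):
    """One drug row: explicit category, dose per procedure (mg), cost (EUR)."""

    category: Literal["anesthetics", "opioids", "antibiotics", "corticosteroids", "other"]
    drug: str
    dose_mg: Decimal = Decimal(0)
    cost: Decimal = Decimal(0)

    @field_validator("dose_mg", "cost", mode="before")
    @classmethod
    def _coerce(cls, v):
        return as_money(v)

    @model_validator(mode="after")
    def _check(self):
        _non_negative("dose_mg", self.dose_mg)
        _non_negative("cost", self.cost)
        return self


class DrugCategoryPolicy(_Base):
    """How the lines of one drug category aggregate to a category cost.

    ``mean_of_alternatives`` models mutually exclusive alternatives used with
    equal likelihood; ``sum_of_lines`` models co-administered drugs;
    ``printed_override`` pins a published category cost that cannot be
    reproduced from the lines (the source's usage weighting is unstated).
    """

    category: Literal["anesthetics", "opioids", "antibiotics", "corticosteroids", "other"]
    aggregation: Literal["mean_of_alternatives", "sum_of_lines", "printed_override"]
    override_cost: Optional[Decimal] = None

    @field_validator("override_cost", mode="before")
    @classmethod
    def _coerce(cls, v):
        return None if v is None else as_money(v)

    @model_validator(mode="after")
    def _check(self):
        if (self.aggregation == "printed_override") != (self.override_cost is not None):
            raise ValueError(
                f"category {self.category!r}: override_cost must be present "
                "iff aggregation is printed_override"
            )
        _non_negative("override_cost", self.override_cost)
        return self


class StaffLine(_Base):
    """One professional role: mean headcount and engagement-time-weighted cost."""

    role: str
    headcount: Decimal = Decimal(1)
    cost: Decimal = Decimal(0)

    @field_validator("headcount", "cost", mode="before")
    @classmethod
    def _coerce(cls, v):
        return as_money(v)

    @model_validator(mode="after")
    def _check(self):
        _non_negative("headcount", self.headcount)
        _non_negative("cost", self.cost)
        return self


class FacilityParams(_Base):
    """Operating-room occupation and hospital stay.

    Day-hospital procedures have no operating room (all ``or_*`` fields
    absent).  When both a duration and a per-unit rate are given their product
    must reconcile with the stated cost (checked by :func:`reconcile`).
    """

    or_minutes: Optional[Decimal] = None
    or_cost: Optional[Decimal] = None
    or_rate_per_minute: Optional[Decimal] = None
    stay_days: Decimal = Decimal(0)
    stay_cost: Optional[Decimal] = None
    stay_rate_per_day: Optional[Decimal] = None

    @field_validator(
        "or_minutes", "or_cost", "or_rate_per_minute",
        "stay_days", "stay_cost", "stay_rate_per_day", mode="before",
    )
    @classmethod
    def _coerce(cls, v):
        return None if v is None else as_money(v)

    @model_validator(mode="after")
    def _check(self):
        for name in ("or_minutes", "or_cost", "or_rate_per_minute",
                     "stay_days", "stay_cost", "stay_rate_per_day"):
            _non_negative(name, getattr(self, name))
        return self


class FollowUpCourse(_Base):
    """A named post-operative course and the fraction of patients on it."""

    name: Literal["standard", "acute_complications", "chronic_complications"]
    frequency: Decimal
    items: list[CostItem] = Field(default_factory=list)
    printed_total: Optional[Decimal] = None

    @field_validator("frequency", "printed_total", mode="before")
    @classmethod
    def _coerce(cls, v):
        return None if v is None else as_money(v)

    @model_validator(mode="after")
    def _check(self):
        if not (0 <= self.frequency <= 1):
            raise ValueError(f"course {self.name!r}: frequency must be in [0, 1]")
        _non_negative("printed_total", self.printed_total)
        return self


class IndirectCostParams(_Base):
    """Human-capital productivity-loss inputs.

    Lost time is (hospitalization + convalescence) days at
    ``hours_lost_per_day`` hours valued at the weighted ``hourly_wage``; a
    fraction ``caregiver_share`` of patients is accompanied by a caregiver who
    loses the same time.  ``printed_patient_loss`` pins a published patient
    term whose internal weighting is not recoverable from the scalar inputs.
    """

    hosp_days: Decimal = Decimal(0)
    convalescence_days: Decimal = Decimal(0)
    hours_lost_per_day: Decimal = Decimal(5)
    hourly_wage: Decimal = Decimal("14.05")
    caregiver_share: Decimal = Decimal(0)
    printed_patient_loss: Optional[Decimal] = None
    printed_caregiver_loss: Optional[Decimal] = None

    @field_validator(
        "hosp_days", "convalescence_days", "hours_lost_per_day", "hourly_wage",
        "caregiver_share", "printed_patient_loss", "printed_caregiver_loss",
        mode="before",
    )
    @classmethod
    def _coerce(cls, v):
        return None if v is None else as_money(v)

    @model_validator(mode="after")
    def _check(self):
        for name in ("hosp_days", "convalescence_days", "hours_lost_per_day",
                     "hourly_wage", "caregiver_share",
                     "printed_patient_loss", "printed_caregiver_loss"):
            _non_negative(name, getattr(self, name))
        if self.caregiver_share > 1:
            raise ValueError("caregiver_share must be <= 1")
        return self


class InterventionDataset(_Base):
    """The complete declarative description of one treatment's cost drivers.

    Beyond the raw rows, a dataset can carry transcription metadata:

    ``phase_overrides``
        phase name -> cost; an override always wins over the item sum, used
        when a published aggregate cannot be reconstructed from its rows.
    ``printed_phase_totals``
        phase name -> published phase total; honored by the engine in
        fidelity mode (reconciliation-checked), ignored in raw mode.
    ``followup_residual``
        flat cost added to the follow-up mixture (a published subtotal's
        unexplained remainder, kept visible rather than folded into a course).
    ``summary_reference``
        published summary-level values (comparative-table rows, subtotals,
        grand totals) used only for reconciliation reports and tests, never
        as engine inputs.
    """

    name: str
    prehosp_items: list[CostItem] = Field(default_factory=list)
    drug_lines: list[DrugLine] = Field(default_factory=list)
    drug_policies: list[DrugCategoryPolicy] = Field(default_factory=list)
    material_items: list[CostItem] = Field(default_factory=list)
    staff_lines: list[StaffLine] = Field(default_factory=list)
    facility: FacilityParams = Field(default_factory=FacilityParams)
    followup_courses: list[FollowUpCourse] = Field(default_factory=list)
    indirect: IndirectCostParams = Field(default_factory=IndirectCostParams)
    retreatment_rate: Decimal = Decimal(0)
    phase_overrides: dict[str, Decimal] = Field(default_factory=dict)
    printed_phase_totals: dict[str, Decimal] = Field(default_factory=dict)
    followup_residual: Decimal = Decimal(0)
    summary_reference: dict[str, Decimal] = Field(default_factory=dict)

    @field_validator("retreatment_rate", "followup_residual", mode="before")
    @classmethod
    def _coerce(cls, v):
        return as_money(v)

    @field_validator("phase_overrides", "printed_phase_totals", "summary_reference",
                     mode="before")
    @classmethod
    def _coerce_map(cls, v):
        return {k: as_money(x) for k, x in dict(v).items()}

    @model_validator(mode="after")
    def _check(self):
        errors: list[str] = []
        if not (0 <= self.retreatment_rate < 1):
            errors.append(
                f"retreatment_rate must be in [0, 1), got {self.retreatment_rate}"
            )
        if self.followup_residual < 0:
            errors.append("followup_residual must be >= 0")
        fsum = sum((c.frequency for c in self.followup_courses), Decimal(0))
        if fsum > 1 + RECONCILE_TOLERANCE / 100:
            errors.append(
                f"follow-up course frequencies must sum to <= 1, got {fsum}"
            )
        seen = [c.name for c in self.followup_courses]
        if len(seen) != len(set(seen)):
            errors.append("duplicate follow-up course names")
        for phase in list(self.phase_overrides) + list(self.printed_phase_totals):
            if phase not in PHASE_NAMES:
                errors.append(f"unknown phase name {phase!r}")
        if errors:
            raise ValueError("; ".join(errors))
        return self

    # -- convenience -----------------------------------------------------
    def course(self, name: str) -> FollowUpCourse:
        for c in self.followup_courses:
            if c.name == name:
                return c
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconciliationNote:
    """One printed-vs-recomputed comparison.

    ``level`` is "ok" when the absolute difference is within the tolerance
    and "mismatch" otherwise; mismatches are documentation of the source's
    internal inconsistencies, not fatal errors.
    """

    location: str
    printed: Decimal
    computed: Decimal
    level: str

    @property
    def delta(self) -> Decimal:
        return to_cents(self.computed - self.printed)


def _note(location: str, printed: Decimal, computed: Decimal,
          tolerance: Decimal = RECONCILE_TOLERANCE) -> ReconciliationNote:
    level = "ok" if abs(computed - printed) <= tolerance else "mismatch"
    return ReconciliationNote(location, printed, to_cents(computed), level)


def reconcile(dataset: InterventionDataset) -> list[ReconciliationNote]:
    """Check every printed aggregate in a dataset against its recomputed sum.

    Covers course totals vs item sums, phase printed totals vs recomputed
    phase costs, facility duration x rate vs stated cost, productivity
    printed terms vs the raw formula, and any summary_reference entries that
    map to table-level totals.  Returns one note per comparison.
    """
    from . import engine  # late import: engine depends on these types

    notes: list[ReconciliationNote] = []
    for course in dataset.followup_courses:
        if course.printed_total is not None and course.items:
            notes.append(_note(
                f"{dataset.name}: follow-up course {course.name!r} total",
                course.printed_total,
                engine.phase_cost(course.items),
            ))
    computed_phases = engine.base_phase_costs(dataset, mode="raw")
    for phase, printed in dataset.printed_phase_totals.items():
        notes.append(_note(
            f"{dataset.name}: printed {phase} total", printed, computed_phases[phase]
        ))
    fac = dataset.facility
    if fac.stay_cost is not None and fac.stay_rate_per_day is not None:
        notes.append(_note(
            f"{dataset.name}: hospital stay days x rate",
            fac.stay_cost, fac.stay_days * fac.stay_rate_per_day,
        ))
    if (fac.or_cost is not None and fac.or_rate_per_minute is not None
            and fac.or_minutes is not None):
        notes.append(_note(
            f"{dataset.name}: operating room minutes x rate",
            fac.or_cost, fac.or_minutes * fac.or_rate_per_minute,
        ))
    ind = dataset.indirect
    if ind.printed_patient_loss is not None:
        raw_patient = ((ind.hosp_days + ind.convalescence_days)
                       * ind.hours_lost_per_day * ind.hourly_wage)
        # printed patient terms embed an employment-mix weighting the scalar
        # inputs cannot carry; allow a wider (0.5%) band before flagging
        tol = max(RECONCILE_TOLERANCE, raw_patient * Decimal("0.005"))
        notes.append(_note(
            f"{dataset.name}: printed patient productivity loss",
            ind.printed_patient_loss, raw_patient, tolerance=tol,
        ))
    if ind.printed_caregiver_loss is not None and ind.printed_patient_loss is not None:
        notes.append(_note(
            f"{dataset.name}: printed caregiver productivity loss",
            ind.printed_caregiver_loss,
            ind.caregiver_share * ind.printed_patient_loss,
        ))
    notes.extend(engine.reconcile_summary(dataset))
    return notes


# ---------------------------------------------------------------------------
# Serialization (YAML document / CSV bundle / JSON export)
# ---------------------------------------------------------------------------

def _dec_to_str(v: Decimal) -> str:
    return format(v, "f")


def _dump_value(v):
    if isinstance(v, Decimal):
        return _dec_to_str(v)
    if isinstance(v, dict):
        return {k: _dump_value(x) for k, x in v.items()}
    if isinstance(v, list):
        return [_dump_value(x) for x in v]
    if isinstance(v, BaseModel):
        return _dump_value(v.model_dump())
    return v


def dataset_to_dict(dataset: InterventionDataset) -> dict:
    """Plain dict with all Decimals rendered as exact decimal strings."""
    return _dump_value(dataset.model_dump())


def dataset_from_dict(payload: dict) -> InterventionDataset:
    try:
        return InterventionDataset.model_validate(payload)
    except Exception as exc:  # pydantic collects every violation already
        raise DatasetValidationError(str(exc)) from exc


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "csv-bundle"
    if path.suffix.lower() in (".yaml", ".yml"):
        return "yaml"
    if path.suffix.lower() == ".json":
        return "json"
    raise DatasetFormatError(f"cannot infer format of {path}")


def load_dataset(path, format: Optional[str] = None) -> InterventionDataset:
    """Read a dataset from a YAML file, JSON file, or CSV-bundle directory."""
    path = Path(path)
    if not path.exists():
        raise DatasetFormatError(f"{path} does not exist")
    fmt = format or _detect_format(path)
    if fmt == "yaml":
        try:
            payload = yaml.safe_load(path.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise DatasetFormatError(f"{path}: invalid YAML: {exc}") from exc
    elif fmt == "json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise DatasetFormatError(f"{path}: invalid JSON: {exc}") from exc
    elif fmt == "csv-bundle":
        payload = _read_csv_bundle(path)
    else:
        raise DatasetFormatError(f"unknown format {fmt!r}")
    if not isinstance(payload, dict):
        raise DatasetFormatError(f"{path}: top level must be a mapping")
    return dataset_from_dict(payload)


def write_dataset(dataset: InterventionDataset, path, format: Optional[str] = None):
    """Write a dataset; ``load_dataset(write_dataset(d)) == d`` field for field."""
    path = Path(path)
    fmt = format or ("csv-bundle" if path.suffix == "" else _detect_format(path))
    payload = dataset_to_dict(dataset)
    try:
        if fmt == "yaml":
            path.write_text(
                yaml.safe_dump(payload, sort_keys=False, allow_unicode=True),
                encoding="utf-8",
            )
        elif fmt == "json":
            path.write_text(json.dumps(_json_export(dataset), indent=2),
                            encoding="utf-8")
        elif fmt == "csv-bundle":
            _write_csv_bundle(dataset, path)
        else:
            raise DatasetFormatError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def _json_export(dataset: InterventionDataset) -> dict:
    """JSON form: every money field as a 2-decimal string plus exact cents."""

    def enrich(obj):
        if isinstance(obj, dict):
            return {k: enrich(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [enrich(v) for v in obj]
        if isinstance(obj, str):
            try:
                d = Decimal(obj)
            except Exception:
                return obj
            return {"value": _dec_to_str(to_cents(d)),
                    "exact": _dec_to_str(d)}
        return obj

    out = dataset_to_dict(dataset)
    return {k: (v if k == "name" else enrich(v)) for k, v in out.items()}


# -- CSV bundle dialect ------------------------------------------------------
#
# Directory of UTF-8 CSVs with mandatory header rows and dot decimals:
#   prehosp.csv / materials.csv : label,quantity,unit_cost,weighted_cost_override
#   drugs.csv                   : category,drug,dose_mg,cost
#   drug_policies.csv           : category,aggregation,override_cost
#   staff.csv                   : role,headcount,cost
#   followup_<course>.csv       : label,quantity,unit_cost,weighted_cost_override
#   params.csv                  : key,value  (scalars, facility.*, indirect.*,
#                                 phase_override.*, printed_total.*, summary.*,
#                                 followup_frequency.* , followup_printed_total.*)

_ITEM_COLS = ("label", "quantity", "unit_cost", "weighted_cost_override")


def _write_rows(path: Path, header: Iterable[str], rows: Iterable[dict]):
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=list(header))
        w.writeheader()
        for row in rows:
            w.writerow({k: ("" if v is None else v) for k, v in row.items()})


def _item_rows(items: list[CostItem]):
    return [_dump_value(i.model_dump()) for i in items]


def _write_csv_bundle(dataset: InterventionDataset, root: Path):
    root.mkdir(parents=True, exist_ok=True)
    _write_rows(root / "prehosp.csv", _ITEM_COLS, _item_rows(dataset.prehosp_items))
    _write_rows(root / "materials.csv", _ITEM_COLS, _item_rows(dataset.material_items))
    _write_rows(root / "drugs.csv", ("category", "drug", "dose_mg", "cost"),
                [_dump_value(l.model_dump()) for l in dataset.drug_lines])
    _write_rows(root / "drug_policies.csv",
                ("category", "aggregation", "override_cost"),
                [_dump_value(p.model_dump()) for p in dataset.drug_policies])
    _write_rows(root / "staff.csv", ("role", "headcount", "cost"),
                [_dump_value(l.model_dump()) for l in dataset.staff_lines])
    for course in dataset.followup_courses:
        _write_rows(root / f"followup_{course.name}.csv", _ITEM_COLS,
                    _item_rows(course.items))
    params: list[tuple[str, str]] = [("name", dataset.name)]
    for key in ("retreatment_rate", "followup_residual"):
        params.append((key, _dec_to_str(getattr(dataset, key))))
    for field, v in dataset.facility.model_dump().items():
        if v is not None:
            params.append((f"facility.{field}", _dec_to_str(v)))
    for field, v in dataset.indirect.model_dump().items():
        if v is not None:
            params.append((f"indirect.{field}", _dec_to_str(v)))
    for course in dataset.followup_courses:
        params.append((f"followup_frequency.{course.name}",
                       _dec_to_str(course.frequency)))
        if course.printed_total is not None:
            params.append((f"followup_printed_total.{course.name}",
                           _dec_to_str(course.printed_total)))
    for phase, v in dataset.phase_overrides.items():
        params.append((f"phase_override.{phase}", _dec_to_str(v)))
    for phase, v in dataset.printed_phase_totals.items():
        params.append((f"printed_total.{phase}", _dec_to_str(v)))
    for key, v in dataset.summary_reference.items():
        params.append((f"summary.{key}", _dec_to_str(v)))
    _write_rows(root / "params.csv", ("key", "value"),
                [{"key": k, "value": v} for k, v in params])


def _read_rows(path: Path) -> list[dict]:
    if not path.exists():
        return []
    try:
        with path.open(newline="", encoding="utf-8") as fh:
            return [
                {k: (None if v == "" else v) for k, v in row.items()}
                for row in csv.DictReader(fh)
            ]
    except csv.Error as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def _read_csv_bundle(root: Path) -> dict:
    params: dict[str, str] = {}
    for row in _read_rows(root / "params.csv"):
        if "key" not in row or "value" not in row:
            raise DatasetFormatError(f"{root/'params.csv'}: needs key,value header")
        params[row["key"]] = row["value"]

    def collect(prefix: str) -> dict:
        n = len(prefix)
        return {k[n:]: v for k, v in params.items() if k.startswith(prefix)}

    courses = []
    for name in COURSE_NAMES:
        freq = params.get(f"followup_frequency.{name}")
        items = _read_rows(root / f"followup_{name}.csv")
        if freq is None and not items:
            continue
        if freq is None:
            raise DatasetFormatError(
                f"{root}: followup_{name}.csv present but "
                f"followup_frequency.{name} missing from params.csv"
            )
        courses.append({
            "name": name, "frequency": freq, "items": items,
            "printed_total": params.get(f"followup_printed_total.{name}"),
        })
    payload = {
        "name": params.get("name", root.name),
        "prehosp_items": _read_rows(root / "prehosp.csv"),
        "material_items": _read_rows(root / "materials.csv"),
        "drug_lines": _read_rows(root / "drugs.csv"),
        "drug_policies": _read_rows(root / "drug_policies.csv"),
        "staff_lines": _read_rows(root / "staff.csv"),
        "followup_courses": courses,
        "facility": collect("facility."),
        "indirect": collect("indirect."),
        "retreatment_rate": params.get("retreatment_rate", "0"),
        "followup_residual": params.get("followup_residual", "0"),
        "phase_overrides": collect("phase_override."),
        "printed_phase_totals": collect("printed_total."),
        "summary_reference": collect("summary."),
    }
    return payload


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

BUNDLED_NAMES = ("total_thyroidectomy", "hemithyroidectomy", "thermal_ablation")


def bundled_dataset(name: str) -> InterventionDataset:
    """Load one bundled treatment dataset by name."""
    if name not in BUNDLED_NAMES:
        raise KeyError(f"unknown bundled dataset {name!r}; choose from {BUNDLED_NAMES}")
    ref = resources.files("abcost.data").joinpath(f"{name}.yaml")
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return dataset_from_dict(payload)


def bundled_datasets() -> list[InterventionDataset]:
    """The three bundled treatment datasets (thyroidectomy, hemi, ablation)."""
    return [bundled_dataset(name) for name in BUNDLED_NAMES]
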
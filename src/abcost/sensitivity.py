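"""Uncertainty analysis over the costing model.

The source analysis is deterministic, but two of its inputs are explicitly
uncertain: device prices fluctuate, and the recurrence risk of ablative
procedures (which drives the retreatment uplift) spans roughly 5-25%.  This
module provides the standard decision-analytic toolkit over any dataset
parameter: one-way sweeps, tornado ranking by induced total-cost range, and
Monte Carlo propagation.

Parameters are addressed with dotted paths into the dataset, with
``[key]`` selecting a list element by its label/role/drug/name, e.g.::

    retreatment_rate
    facility.stay_days
    indirect.hourly_wage
    material_items[Gauze].weighted_cost_override
    followup_courses[standard].frequency

Evaluations default to raw mode so that changes to quantities and prices
actually flow into the total (fidelity mode would honor printed aggregates
and mask them).  The dataset passed in is never mutated.

Randomness contract: one master seed governs a run; each parameter spec
draws from its own substream keyed by position, so appending a spec leaves
the draws of the others unchanged.
"""

from __future__ import annotations

import re
from decimal import Decimal
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cost_tables import (
    ConfigurationError,
    DatasetValidationError,
    InterventionDataset,
    as_money,
)
from .engine import intervention_total

__all__ = [
    "ParameterSpec",
    "SensitivityResult",
    "MonteCarloSummary",
    "get_param",
    "set_param",
    "one_way_sweep",
    "tornado",
    "monte_carlo",
]

DISTRIBUTIONS = ("fixed", "uniform", "triangular", "normal_truncated_at_zero")


class ParameterSpec(BaseModel):
    """One uncertain parameter: where it lives, its range, its distribution.

    With no range given, bounds default to +/-20% around the dataset's
    current value (resolved at evaluation time).
    """

    model_config = ConfigDict(frozen=True)

    path: str
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: str = "uniform"
    dist_params: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"distribution must be one of {DISTRIBUTIONS}, "
                f"got {self.distribution!r}"
            )
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"{self.path}: low > high")
        if self.distribution == "normal_truncated_at_zero":
            sd = self.dist_params.get("sd")
            if sd is None or sd < 0:
                raise ValueError(f"{self.path}: normal distribution needs sd >= 0")
        return self

    def bounds(self, dataset: InterventionDataset) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            return float(self.low), float(self.high)
        current = float(get_param(dataset, self.path))
        return 0.8 * current, 1.2 * current


class SensitivityResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    parameter: str
    totals: list[tuple[float, float]]  # (parameter value, grand total), sorted
    range_width: float


class MonteCarloSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int
    seed: int
    mean_total: float
    sd_total: float
    quantiles: dict[str, float]  # keys "2.5%", "50%", "97.5%"


# ---------------------------------------------------------------------------
# Dotted-path resolution
# ---------------------------------------------------------------------------

_SEGMENT = re.compile(r"^(?P<name>[A-Za-z_][A-Za-z0-9_]*)(\[(?P<key>[^\]]+)\])?$")
_MATCH_FIELDS = ("label", "role", "drug", "name", "category")


def _walk(dataset: InterventionDataset, path: str):
    """Yield (parent, final attribute name) for a dotted path."""
    obj = dataset
    segments = path.split(".")
    for i, segment in enumerate(segments):
        m = _SEGMENT.match(segment.strip())
        if not m:
            raise ConfigurationError(f"cannot parse path segment {segment!r}")
        name, key = m.group("name"), m.group("key")
        if not hasattr(obj, name):
            raise ConfigurationError(f"{path}: no field {name!r} on {type(obj).__name__}")
        last = i == len(segments) - 1
        if key is None and last:
            return obj, name
        obj = getattr(obj, name)
        if key is not None:
            obj = _index(obj, key, path)
            if last:
                raise ConfigurationError(f"{path}: must end on a scalar field")
    raise ConfigurationError(f"{path}: must end on a scalar field")


def _index(seq, key: str, path: str):
    if not isinstance(seq, list):
        raise ConfigurationError(f"{path}: [{key}] applied to a non-list")
    if key.lstrip("-").isdigit():
        try:
            return seq[int(key)]
        except IndexError:
            raise ConfigurationError(f"{path}: index {key} out of range") from None
    for element in seq:
        for field in _MATCH_FIELDS:
            if getattr(element, field, None) == key:
                return element
    raise ConfigurationError(f"{path}: no element matching {key!r}")


def get_param(dataset: InterventionDataset, path: str):
    parent, name = _walk(dataset, path)
    value = getattr(parent, name)
    if value is None:
        raise ConfigurationError(f"{path}: field is unset")
    return value


def set_param(dataset: InterventionDataset, path: str, value) -> None:
    """Set a numeric field in place (dataset should be a working copy)."""
    parent, name = _walk(dataset, path)
    current = getattr(parent, name)
    if isinstance(current, Decimal) or current is None:
        value = as_money(float(value))
    setattr(parent, name, value)


# ---------------------------------------------------------------------------
# One-way sweep and tornado
# ---------------------------------------------------------------------------

def _evaluate(working: InterventionDataset, spec_path: str, value: float,
              perspective, mode: str) -> float:
    set_param(working, spec_path, value)
    return float(intervention_total(working, perspective, mode=mode).grand_total)


def one_way_sweep(
    dataset: InterventionDataset,
    spec: ParameterSpec,
    steps: int = 11,
    perspective="societal",
    mode: str = "raw",
) -> SensitivityResult:
    """Evaluate the grand total at evenly spaced parameter values.

    Endpoints are evaluated directly at ``low`` and ``high`` (no
    interpolation); the input dataset is left untouched.
    """
    if steps < 2:
        raise ConfigurationError("steps must be >= 2")
    low, high = spec.bounds(dataset)
    working = dataset.model_copy(deep=True)
    totals = [
        (float(v), _evaluate(working, spec.path, float(v), perspective, mode))
        for v in np.linspace(low, high, steps)
    ]
    totals.sort(key=lambda t: t[0])
    values = [t[1] for t in totals]
    return SensitivityResult(
        parameter=spec.path, totals=totals,
        range_width=max(values) - min(values),
    )


def tornado(
    dataset: InterventionDataset,
    specs: Sequence[ParameterSpec],
    perspective="societal",
    mode: str = "raw",
) -> list[SensitivityResult]:
    """Rank parameters by the total-cost range induced over [low, high].

    One low and one high evaluation per spec; sorted by descending range
    width, ties broken by parameter path.
    """
    if not specs:
        raise ConfigurationError("tornado needs at least one parameter spec")
    results = [one_way_sweep(dataset, spec, steps=2,
                             perspective=perspective, mode=mode)
               for spec in specs]
    return sorted(results, key=lambda r: (-r.range_width, r.parameter))


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def _draw(spec: ParameterSpec, low: float, high: float, n: int,
          rng: np.random.Generator) -> np.ndarray:
    if spec.distribution == "fixed":
        value = spec.dist_params.get("value", low)
        return np.full(n, value)
    if spec.distribution == "uniform":
        return rng.uniform(low, high, size=n)
    if spec.distribution == "triangular":
        mode_v = spec.dist_params.get("mode", (low + high) / 2)
        if not (low <= mode_v <= high):
            raise DatasetValidationError(
                f"{spec.path}: triangular mode {mode_v} outside [{low}, {high}]"
            )
        return rng.triangular(low, mode_v, high, size=n)
    # normal truncated at zero: rejection sampling
    mean = spec.dist_params.get("mean", (low + high) / 2)
    sd = spec.dist_params["sd"]
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.normal(mean, sd, size=n - filled)
        keep = draws[draws >= 0]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def monte_carlo(
    dataset: InterventionDataset,
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
    perspective="societal",
    mode: str = "raw",
) -> MonteCarloSummary:
    """Propagate independent parameter draws through the costing engine.

    Reproducible given (specs, n, seed): spec ``i`` draws from the substream
    ``SeedSequence(seed).spawn()[i]``.  With every distribution fixed the
    summary degenerates to the deterministic total with zero spread.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not specs:
        raise ConfigurationError("monte_carlo needs at least one parameter spec")
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    draws = []
    for spec, stream in zip(specs, streams):
        low, high = spec.bounds(dataset)
        draws.append(_draw(spec, low, high, n, np.random.default_rng(stream)))

    working = dataset.model_copy(deep=True)
    totals = np.empty(n)
    for i in range(n):
        for spec, column in zip(specs, draws):
            set_param(working, spec.path, column[i])
        totals[i] = float(
            intervention_total(working, perspective, mode=mode).grand_total
        )
    q = np.percentile(totals, [2.5, 50, 97.5])
    return MonteCarloSummary(
        n=n,
        seed=seed,
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)) if n > 1 else 0.0,
        quantiles={"2.5%": float(q[0]), "50%": float(q[1]), "97.5%": float(q[2])},
    )
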
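"""Cross-cohort feasibility engine: availability counts and filter funnels.

Planning a multi-cohort analysis starts with a feasibility question: how many
participants, in which cohorts, actually have data for the variable
combination I need?  This module answers it over curated datasets and a set
of *harmonised variables* — constructs declared equivalent across cohorts,
each addressed by one label with per-cohort object-name bindings (e.g.
"Smoking status" -> ``AAA_SMOKSTAT_0_1`` in one cohort, ``BBB_SMK_0_1`` in
another).

Two primitives:

* :func:`availability` — per variable x cohort, the number of participants
  with data (informative non-response counts as data present; only the
  missing sentinel counts as absent).
* :func:`funnel` — sequential participant counts under conjunctive filters
  ("aged 50+, never-smoker, APOE4 carrier"), per cohort and pooled, exposing
  how quickly a variable combination erodes the usable sample.

Only counts leave this API — no individual-level data — mirroring the
access-controlled portal the engine is designed for.

For cross-cohort comparability of scale variables, :func:`standardise`
offers z-scoring and min-max rescaling of curated numeric columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curate import CuratedDataset, ID_COLUMN
from .errors import DegenerateScaleError, FilterConfigError, IntegrityError
from .recode import is_missing, _code_key
from .taxonomy import NodePath

__all__ = [
    "HarmonisedVariable",
    "FilterStep",
    "FunnelStepResult",
    "FunnelResult",
    "AvailabilityMatrix",
    "availability",
    "funnel",
    "standardise",
]

_PREDICATE_OPS = ("ge", "le", "eq", "in", "nonmissing", "missing")


@dataclass(frozen=True)
class HarmonisedVariable:
    """A construct declared equivalent across cohorts.

    ``per_cohort_object`` binds each cohort code to the curated object name
    realising the construct there; a cohort without a binding simply has no
    data for it (availability 0, flagged absent).
    """

    label: str
    per_cohort_object: Mapping[str, str]
    taxonomy_path: NodePath = ()
    transform: str | None = None  # None | "zscore" | "rescale"

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_cohort_object", dict(self.per_cohort_object))

    def column_for(self, cohort_code: str) -> str | None:
        return dict(self.per_cohort_object).get(cohort_code.upper())


@dataclass(frozen=True)
class FilterStep:
    """One conjunctive filter: a harmonised variable and a predicate.

    ``op`` is one of ``ge``, ``le``, ``eq`` (with ``value``), ``in`` (with a
    set ``values``), ``nonmissing`` or ``missing``.  A missing value fails
    every predicate except ``missing`` — funnels count usable complete data
    by default.
    """

    variable: HarmonisedVariable
    op: str
    value: Any = None
    values: frozenset | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.op not in _PREDICATE_OPS:
            raise FilterConfigError(f"unknown predicate op {self.op!r}; expected {_PREDICATE_OPS}")
        if self.op in ("ge", "le", "eq") and self.value is None:
            raise FilterConfigError(f"predicate {self.op!r} needs a value")
        if self.op == "in":
            if not self.values:
                raise FilterConfigError("predicate 'in' needs a non-empty value set")
            object.__setattr__(self, "values", frozenset(self.values))

    @property
    def label(self) -> str:
        if self.description:
            return self.description
        if self.op in ("nonmissing", "missing"):
            return f"{self.variable.label} {self.op}"
        if self.op == "in":
            return f"{self.variable.label} in {sorted(map(str, self.values or ()))}"
        sym = {"ge": ">=", "le": "<=", "eq": "="}[self.op]
        return f"{self.variable.label} {sym} {self.value}"


@dataclass
class FunnelStepResult:
    step: FilterStep
    per_cohort: dict[str, int]
    pooled: int


@dataclass
class FunnelResult:
    """Ordered per-step counts; pooled = sum over cohorts at every step and
    counts never increase down the funnel."""

    base: dict[str, int]
    base_pooled: int
    steps: list[FunnelStepResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "base": {"per_cohort": self.base, "pooled": self.base_pooled},
            "steps": [
                {"label": s.step.label, "per_cohort": s.per_cohort, "pooled": s.pooled}
                for s in self.steps
            ],
        }


@dataclass
class AvailabilityMatrix:
    """Participants with data, by harmonised variable (rows) x cohort
    (columns).  ``absent`` flags (variable label, cohort) pairs where the
    variable has no object bound or the bound column is not in the table."""

    counts: pd.DataFrame
    absent: set[tuple[str, str]] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "counts": {
                var: {c: int(self.counts.loc[var, c]) for c in self.counts.columns}
                for var in self.counts.index
            },
            "absent": sorted(list(self.absent)),
        }


def _check_cohorts(cohorts: Sequence[CuratedDataset]) -> None:
    seen = set()
    for ds in cohorts:
        if ds.cohort_code in seen:
            raise IntegrityError(f"cohort code {ds.cohort_code} appears twice")
        seen.add(ds.cohort_code)
        if ID_COLUMN in ds.table.columns and ds.table[ID_COLUMN].duplicated().any():
            raise IntegrityError(f"cohort {ds.cohort_code}: duplicate participant ids")


def _present_mask(series: pd.Series) -> np.ndarray:
    return ~series.map(is_missing).to_numpy(dtype=bool)


def availability(
    cohorts: Sequence[CuratedDataset], variables: Sequence[HarmonisedVariable]
) -> AvailabilityMatrix:
    """Count participants with non-missing data per variable and cohort.

    Informative non-response codes are values, hence counted as present;
    an unbound or missing column yields 0 and an ``absent`` flag rather than
    an error, so a partial harmonisation is still explorable.
    """
    _check_cohorts(cohorts)
    codes = [ds.cohort_code for ds in cohorts]
    data: dict[str, list[int]] = {c: [] for c in codes}
    absent: set[tuple[str, str]] = set()
    for var in variables:
        for ds in cohorts:
            col = var.column_for(ds.cohort_code)
            if col is None or col not in ds.table.columns:
                absent.add((var.label, ds.cohort_code))
                data[ds.cohort_code].append(0)
            else:
                data[ds.cohort_code].append(int(_present_mask(ds.table[col]).sum()))
    counts = pd.DataFrame(data, index=[v.label for v in variables], columns=codes)
    return AvailabilityMatrix(counts=counts, absent=absent)


def _coerce_numeric(series: pd.Series, step: FilterStep) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & ~series.map(is_missing)
    if bad.any():
        raise FilterConfigError(
            f"step {step.label!r}: predicate {step.op!r} needs a numeric variable but "
            f"{int(bad.sum())} non-missing value(s) are non-numeric "
            f"(first: {series[bad].iloc[0]!r})"
        )
    return out


def _step_mask(ds: CuratedDataset, step: FilterStep) -> np.ndarray:
    n = len(ds.table)
    col = step.variable.column_for(ds.cohort_code)
    if col is None or col not in ds.table.columns:
        # an absent variable behaves as all-missing
        if step.op == "missing":
            return np.ones(n, dtype=bool)
        return np.zeros(n, dtype=bool)
    series = ds.table[col]
    present = _present_mask(series)
    if step.op == "nonmissing":
        return present
    if step.op == "missing":
        return ~present
    if step.op in ("ge", "le"):
        try:
            threshold = float(step.value)
        except (TypeError, ValueError):
            raise FilterConfigError(
                f"step {step.label!r}: threshold {step.value!r} is not numeric"
            ) from None
        numeric = _coerce_numeric(series, step).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            cmp = numeric >= threshold if step.op == "ge" else numeric <= threshold
        return present & np.nan_to_num(cmp, nan=False)
    if step.op == "eq":
        key = _code_key(step.value)
        return present & series.map(lambda v: (not is_missing(v)) and _code_key(v) == key).to_numpy(
            dtype=bool
        )
    # op == "in"
    keys = {_code_key(v) for v in (step.values or ())}
    return present & series.map(lambda v: (not is_missing(v)) and _code_key(v) in keys).to_numpy(
        dtype=bool
    )


def funnel(cohorts: Sequence[CuratedDataset], steps: Sequence[FilterStep]) -> FunnelResult:
    """Sequential conjunctive filtering: participants surviving all
    predicates up to step k, per cohort and pooled.

    Counts are of distinct participants (wide curated layout: one row each).
    Counts are non-increasing; pooled = sum of per-cohort counts.
    """
    if not steps:
        raise FilterConfigError("funnel needs at least one step")
    _check_cohorts(cohorts)
    base = {ds.cohort_code: int(len(ds.table)) for ds in cohorts}
    result = FunnelResult(base=base, base_pooled=sum(base.values()))
    masks = {ds.cohort_code: np.ones(len(ds.table), dtype=bool) for ds in cohorts}
    for step in steps:
        per_cohort: dict[str, int] = {}
        for ds in cohorts:
            masks[ds.cohort_code] &= _step_mask(ds, step)
            per_cohort[ds.cohort_code] = int(masks[ds.cohort_code].sum())
        result.steps.append(
            FunnelStepResult(step=step, per_cohort=per_cohort, pooled=sum(per_cohort.values()))
        )
    return result


def standardise(
    values: Sequence | pd.Series,
    transform: str = "zscore",
    *,
    ddof: int = 1,
    minimum: float = 0.0,
    maximum: float = 1.0,
) -> pd.Series:
    """Transform a numeric column for cross-cohort comparability.

    ``zscore`` centres non-missing values to mean 0 and scales to standard
    deviation 1 (sample denominator by default, ``ddof=0`` for population);
    ``rescale`` maps the observed range onto [minimum, maximum].  Missing
    values are preserved.  Fewer than two non-missing values or zero spread
    raise :class:`DegenerateScaleError`.
    """
    series = values if isinstance(values, pd.Series) else pd.Series(list(values), dtype=object)
    numeric = pd.to_numeric(series, errors="coerce")
    mask = ~series.map(is_missing)
    if int(mask.sum()) < 2:
        raise DegenerateScaleError("standardising needs at least 2 non-missing values")
    x = numeric[mask].astype(float)
    if x.isna().any():
        raise DegenerateScaleError("standardising needs a numeric column")
    if transform == "zscore":
        sd = float(x.std(ddof=ddof))
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateScaleError("zero spread: cannot z-score a constant column")
        transformed = (x - float(x.mean())) / sd
    elif transform == "rescale":
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise DegenerateScaleError("zero spread: cannot rescale a constant column")
        transformed = (x - lo) / (hi - lo) * (maximum - minimum) + minimum
    else:
        raise ValueError(f"unknown transform {transform!r}; expected 'zscore' or 'rescale'")
    out = pd.Series([pd.NA] * len(series), dtype=object, index=series.index)
    out[mask] = transformed.astype(float)
    return out
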
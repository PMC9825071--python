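"""Value-labelling conventions and column recoding.

Curation keeps a strict correspondence between native and curated values:

* **Missing** means an absence of recorded data, as indicated by the cohort.
  Internally it is the pandas NA sentinel (anything ``pd.isna`` recognises);
  the Stata-style literal ``"."`` appears only when a curated table is
  serialised to CSV.
* **Informative non-response** ("don't know", "prefer not to answer") is data,
  not missingness: such codes stay as values so that inclusion/exclusion can
  be decided per hypothesis.  An opt-in rule remaps them to a reserved
  negative range for cohorts that want one.
* **Widely used measures** get standard codings: gender is 2 = female,
  1 = male; height is centimetres, weight kilograms (imperial native scales
  are converted with exact legal factors).
* **Native labels are retained**: every recode result carries the untouched
  native value-label map alongside the curated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DatumError,
    GenderMapError,
    RecodeConfigError,
    UnitRegistryError,
)

__all__ = [
    "MISSING",
    "is_missing",
    "ValueLabelMap",
    "RecodeRule",
    "RecodeResult",
    "UNIT_FACTORS",
    "conversion_factor",
    "recode_missing",
    "recode_gender",
    "convert_unit",
    "apply_conventions",
    "FEMALE_CODE",
    "MALE_CODE",
]

#: Canonical in-memory missing sentinel.  Serialised as "." at the CSV
#: boundary only.
MISSING = pd.NA

FEMALE_CODE = 2
MALE_CODE = 1

_FEMALE_LABELS = frozenset({"female", "f", "woman", "women"})
_MALE_LABELS = frozenset({"male", "m", "man", "men"})

#: Exact legal definitions (international inch/pound, imperial stone); the
#: metric targets are the curated units for anthropometry.
UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("inch", "cm"): 2.54,
    ("foot", "cm"): 30.48,
    ("pound", "kg"): 0.45359237,
    ("stone", "kg"): 6.35029318,
}


def is_missing(value: Any) -> bool:
    """True iff *value* is the canonical missing sentinel (scalar)."""
    if isinstance(value, (list, tuple, set, dict, np.ndarray)):
        return False
    res = pd.isna(value)
    return bool(res)


def _code_key(value: Any) -> Any:
    """Comparison key for native value codes.

    CSV round-trips blur ``9`` / ``"9"`` / ``9.0``; numeric-looking codes are
    compared on their numeric value, everything else as a stripped string.
    """
    if isinstance(value, bool):
        return ("b", value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        f = float(value)
        return ("n", f)
    if isinstance(value, str):
        s = value.strip()
        try:
            return ("n", float(s))
        except ValueError:
            return ("s", s)
    return ("s", str(value))


@dataclass(frozen=True)
class ValueLabelMap:
    """Value labels plus the cohort's missing and non-response conventions.

    ``entries`` maps native codes to label text.  ``missing_codes`` are codes
    that denote absence of recorded data; ``nonresponse_codes`` are codes for
    informative non-response and must each carry a label.  The two sets are
    disjoint by construction.
    """

    entries: Mapping[Any, str] = field(default_factory=dict)
    missing_codes: frozenset = frozenset()
    nonresponse_codes: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "missing_codes", frozenset(self.missing_codes))
        object.__setattr__(self, "nonresponse_codes", frozenset(self.nonresponse_codes))
        overlap = {
            c
            for c in self.missing_codes
            if _code_key(c) in {_code_key(n) for n in self.nonresponse_codes}
        }
        if overlap:
            raise RecodeConfigError(
                f"codes {sorted(map(str, overlap))} declared both missing and non-response"
            )
        labelled = {_code_key(c) for c in self.entries}
        unlabelled = [c for c in self.nonresponse_codes if _code_key(c) not in labelled]
        if unlabelled:
            raise RecodeConfigError(
                f"non-response codes must be labelled; missing labels for "
                f"{sorted(map(str, unlabelled))}"
            )

    def label_for(self, code: Any) -> str | None:
        key = _code_key(code)
        for c, lab in self.entries.items():
            if _code_key(c) == key:
                return lab
        return None

    def to_dict(self) -> dict:
        return {
            "entries": {str(k): v for k, v in self.entries.items()},
            "missing_codes": sorted(map(str, self.missing_codes)),
            "nonresponse_codes": sorted(map(str, self.nonresponse_codes)),
        }


@dataclass(frozen=True)
class RecodeRule:
    """One declarative recode step.

    kinds: ``missing`` (params: optional ``codes``), ``gender``,
    ``unit_conversion`` (params: ``source_unit``, ``target_unit``),
    ``passthrough``, ``custom_map`` (params: ``map``, injective on
    non-missing codes), ``nonresponse_remap`` (params: ``map`` to a reserved
    range, opt-in).
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    _KINDS = ("missing", "gender", "unit_conversion", "passthrough", "custom_map",
              "nonresponse_remap")

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        if self.kind not in self._KINDS:
            raise RecodeConfigError(f"unknown rule kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "unit_conversion":
            conversion_factor(self.params.get("source_unit"), self.params.get("target_unit"))
        if self.kind == "custom_map":
            mapping = self.params.get("map")
            if not isinstance(mapping, Mapping) or not mapping:
                raise RecodeConfigError("custom_map rule requires a non-empty 'map' parameter")
            targets = [_code_key(v) for v in mapping.values()]
            if len(set(targets)) != len(targets):
                raise RecodeConfigError("custom_map must be injective on non-missing codes")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}


@dataclass
class RecodeResult:
    """Outcome of recoding one column.

    ``values`` has exactly the input length; ``native_label_map`` is the
    untouched input map (native labels are retained); ``audit`` counts
    affected cells per applied rule.
    """

    values: pd.Series
    label_map: ValueLabelMap
    native_label_map: ValueLabelMap
    audit: dict[str, int] = field(default_factory=dict)


def _as_series(column: Sequence | pd.Series) -> pd.Series:
    if isinstance(column, pd.Series):
        return column.astype(object) if column.dtype != object else column.copy()
    return pd.Series(list(column), dtype=object)


def conversion_factor(source_unit: str | None, target_unit: str | None) -> float:
    """Exact multiplicative factor from *source_unit* to *target_unit*.

    The registry covers inch/foot->cm and pound/stone->kg, their inverses,
    and identity.  Unknown pairs raise :class:`UnitRegistryError`.
    """
    if not source_unit or not target_unit:
        raise UnitRegistryError("unit_conversion requires source_unit and target_unit")
    s, t = source_unit.lower(), target_unit.lower()
    if s == t:
        return 1.0
    if (s, t) in UNIT_FACTORS:
        return UNIT_FACTORS[(s, t)]
    if (t, s) in UNIT_FACTORS:
        return 1.0 / UNIT_FACTORS[(t, s)]
    known = sorted({u for pair in UNIT_FACTORS for u in pair})
    raise UnitRegistryError(f"no conversion {source_unit!r} -> {target_unit!r}; known units: {known}")


# ---------------------------------------------------------------------------
# single-rule operations
# ---------------------------------------------------------------------------

def recode_missing(
    column: Sequence | pd.Series,
    missing_codes: Iterable,
    nonresponse_codes: Iterable = (),
) -> RecodeResult:
    """Map the cohort's native missing codes to the canonical missing
    sentinel.  Non-response codes are never touched; declaring a code in both
    sets is a configuration error."""
    nonresponse_codes = frozenset(nonresponse_codes)
    native_map = ValueLabelMap(
        # placeholder labels: standalone calls pass bare code sets
        entries={c: "non-response" for c in nonresponse_codes},
        missing_codes=frozenset(missing_codes),
        nonresponse_codes=nonresponse_codes,
    )
    series = _as_series(column)
    keys = {_code_key(c) for c in native_map.missing_codes}
    n_hit = 0
    out = []
    for v in series:
        if not is_missing(v) and _code_key(v) in keys:
            out.append(MISSING)
            n_hit += 1
        else:
            out.append(v)
    return RecodeResult(
        values=pd.Series(out, dtype=object, index=series.index),
        label_map=native_map,
        native_label_map=native_map,
        audit={"missing": n_hit},
    )


def find_gender_codes(native_map: ValueLabelMap) -> tuple[Any, Any]:
    """Identify the native (female_code, male_code) from labels.

    Matching is case-insensitive on {female, f, woman} / {male, m, man}.
    Raises :class:`GenderMapError` when neither pole is identifiable, in which
    case the caller must supply an explicit custom_map — positional guessing
    is forbidden.
    """
    female = male = None
    for code, label in native_map.entries.items():
        lab = str(label).strip().casefold()
        if lab in _FEMALE_LABELS:
            female = code
        elif lab in _MALE_LABELS:
            male = code
    if female is None and male is None:
        raise GenderMapError(
            f"no recognisable female/male labels in {dict(native_map.entries)!r}; "
            f"declare an explicit custom_map rule"
        )
    return female, male


def recode_gender(column: Sequence | pd.Series, native_map: ValueLabelMap) -> RecodeResult:
    """Standardise a gender column: female -> 2, male -> 1.

    Codes for other labelled categories are preserved unchanged and counted
    in the audit as unmapped (information is never discarded)."""
    female, male = find_gender_codes(native_map)
    series = _as_series(column)
    fk = _code_key(female) if female is not None else None
    mk = _code_key(male) if male is not None else None
    nr_keys = {_code_key(c) for c in native_map.nonresponse_codes}

    out = []
    n_changed = 0
    unmapped: set = set()
    for v in series:
        if is_missing(v):
            out.append(v)
            continue
        key = _code_key(v)
        if key == fk:
            out.append(FEMALE_CODE)
            n_changed += int(key != _code_key(FEMALE_CODE))
        elif key == mk:
            out.append(MALE_CODE)
            n_changed += int(key != _code_key(MALE_CODE))
        else:
            out.append(v)
            if key not in nr_keys:
                unmapped.add(key)

    entries: dict[Any, str] = {MALE_CODE: "Male", FEMALE_CODE: "Female"}
    std_keys = {fk, mk}
    for code, label in native_map.entries.items():
        if _code_key(code) not in std_keys:
            entries[code] = label
    label_map = ValueLabelMap(
        entries=entries,
        missing_codes=native_map.missing_codes,
        nonresponse_codes=native_map.nonresponse_codes,
    )
    return RecodeResult(
        values=pd.Series(out, dtype=object, index=series.index),
        label_map=label_map,
        native_label_map=native_map,
        audit={"gender": n_changed, "gender_unmapped_categories": len(unmapped)},
    )


def convert_unit(column: Sequence | pd.Series, rule: RecodeRule) -> RecodeResult:
    """Rescale a numeric column by the exact registry factor (e.g. inches to
    centimetres).  Missing passes through; a non-numeric, non-missing cell is
    a datum error carrying its row index.  Values are stored at full float
    precision (rounding is a display concern)."""
    if rule.kind != "unit_conversion":
        raise RecodeConfigError(f"convert_unit needs a unit_conversion rule, got {rule.kind!r}")
    factor = conversion_factor(rule.params.get("source_unit"), rule.params.get("target_unit"))
    series = _as_series(column)
    out = []
    n_conv = 0
    for pos, v in enumerate(series):
        if is_missing(v):
            out.append(v)
            continue
        try:
            x = float(v)
        except (TypeError, ValueError):
            raise DatumError(
                f"row {pos}: cannot convert non-numeric value {v!r} "
                f"({rule.params.get('source_unit')} -> {rule.params.get('target_unit')})",
                row=pos,
            ) from None
        out.append(x * factor)
        n_conv += 1
    units = f"{rule.params.get('source_unit')}->{rule.params.get('target_unit')}"
    empty = ValueLabelMap()
    return RecodeResult(
        values=pd.Series(out, dtype=object, index=series.index),
        label_map=empty,
        native_label_map=empty,
        audit={f"unit_conversion[{units}]": n_conv},
    )


def _apply_custom_map(series: pd.Series, mapping: Mapping, native_map: ValueLabelMap):
    bykey = {_code_key(k): v for k, v in mapping.items()}
    out = []
    n = 0
    for v in series:
        if not is_missing(v) and _code_key(v) in bykey:
            out.append(bykey[_code_key(v)])
            n += 1
        else:
            out.append(v)
    entries = {}
    for code, label in native_map.entries.items():
        entries[bykey.get(_code_key(code), code)] = label
    label_map = ValueLabelMap(
        entries=entries,
        missing_codes=native_map.missing_codes,
        nonresponse_codes=frozenset(
            bykey.get(_code_key(c), c) for c in native_map.nonresponse_codes
        ),
    )
    return pd.Series(out, dtype=object, index=series.index), label_map, n


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def apply_conventions(
    column: Sequence | pd.Series,
    native_map: ValueLabelMap,
    rules: Sequence[RecodeRule],
) -> RecodeResult:
    """Apply an ordered list of rules to one column.

    Audits compose across rules; the native label map is carried through
    untouched.  A failing rule aborts with its index in the message.
    """
    series = _as_series(column)
    current_map = native_map
    audit: dict[str, int] = {}

    for i, rule in enumerate(rules):
        try:
            if rule.kind == "missing":
                codes = rule.params.get("codes", current_map.missing_codes)
                step = recode_missing(series, codes, current_map.nonresponse_codes)
                series = step.values
            elif rule.kind == "gender":
                step = recode_gender(series, current_map)
                series, current_map = step.values, step.label_map
            elif rule.kind == "unit_conversion":
                step = convert_unit(series, rule)
                series = step.values
            elif rule.kind == "passthrough":
                step = RecodeResult(series, current_map, native_map, {"passthrough": 0})
            elif rule.kind == "custom_map":
                series, current_map, n = _apply_custom_map(
                    series, rule.params["map"], current_map
                )
                step = RecodeResult(series, current_map, native_map, {"custom_map": n})
            elif rule.kind == "nonresponse_remap":
                mapping = rule.params.get("map") or {
                    c: t for c, t in zip(sorted(current_map.nonresponse_codes, key=str),
                                         (-8, -9, -7, -6))
                }
                nr = {_code_key(c) for c in current_map.nonresponse_codes}
                mapping = {k: v for k, v in mapping.items() if _code_key(k) in nr}
                series, current_map, n = _apply_custom_map(series, mapping, current_map)
                step = RecodeResult(series, current_map, native_map, {"nonresponse_remap": n})
            else:  # pragma: no cover - RecodeRule forbids unknown kinds
                raise RecodeConfigError(f"unknown rule kind {rule.kind!r}")
        except RecodeConfigError:
            raise
        except (DatumError, GenderMapError, UnitRegistryError) as exc:
            raise type(exc)(f"rule {i} ({rule.kind}): {exc}") from exc
        for k, v in step.audit.items():
            audit[k] = audit.get(k, 0) + v

    return RecodeResult(
        values=series,
        label_map=current_map,
        native_label_map=native_map,
        audit=audit,
    )
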
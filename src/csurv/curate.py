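"""Native -> curated dataset pipeline with data-dictionary generation.

A *mapping spec* declares, for one cohort, how each native variable maps to
the common data model: the canonical object name, the taxonomy object it
instantiates, its value labels and the recode rules to apply.
:func:`apply_mapping` executes the spec against a native table and returns a
:class:`CuratedDataset` — a fully conformant wide table (one row per
participant, columns named by the grammar, wave/serial embedded in the name)
plus a generated data dictionary that carries full question text, units,
curated and native value labels and provenance for every column.

The constrained variable name cannot capture the full context of a
measurement, so the dictionary is a first-class output, not an afterthought.

Curated CSV dialect: UTF-8, comma-separated, RFC 4180 quoting, header row of
canonical names, missing serialised as ``.``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import naming
from .errors import CurationError, IntegrityError, MappingSpecError
from .naming import ObjectName, parse_object_name
from .recode import MISSING, RecodeRule, ValueLabelMap, apply_conventions
from .taxonomy import NodePath, Taxonomy, resolve_path

__all__ = [
    "ID_COLUMN",
    "MISSING_TOKEN",
    "VariableMapping",
    "MappingSpec",
    "DictionaryEntry",
    "CuratedDataset",
    "load_mapping_spec",
    "apply_mapping",
    "build_dictionary",
    "validate_curated",
    "write_curated",
    "read_curated_csv",
]

#: Curated participant-identifier column; excluded from grammar checks.
ID_COLUMN = "id"
#: Serialised missing token (CSV boundary only).
MISSING_TOKEN = "."

_MISSING_NOTE = "missing (absence of recorded data) serialised as '.'"


@dataclass
class VariableMapping:
    """Binding of one native variable to one curated object."""

    native_name: str
    object_name: ObjectName
    taxonomy_path: NodePath
    full_text: str = ""
    units: str = ""
    value_labels: ValueLabelMap = field(default_factory=ValueLabelMap)
    rules: list[RecodeRule] = field(default_factory=list)
    diagnosed_exempt: bool = False
    annotations: str = ""

    @property
    def modality(self) -> str:
        return self.object_name.modality


@dataclass
class MappingSpec:
    """Per-cohort curation declaration.

    Invariants (checked by :meth:`validate`): object names unique within the
    spec (case-insensitive — canonical names, so plain equality), and the
    cohort code consistent across every object name.
    """

    cohort_code: str
    spec_version: str = "1"
    id_column: str = ID_COLUMN
    mappings: list[VariableMapping] = field(default_factory=list)

    def validate(self, taxonomy: Taxonomy | None = None) -> None:
        code = self.cohort_code.upper()
        if not (len(code) == 3 and code.isalpha()):
            raise MappingSpecError(f"cohort_code must be 3 alphabetic characters, got {self.cohort_code!r}")
        seen: dict[str, str] = {}
        for m in self.mappings:
            name = m.object_name.name
            if m.object_name.cohort != code:
                raise MappingSpecError(
                    f"object name {name} carries cohort {m.object_name.cohort}, spec says {code}"
                )
            key = name.casefold()
            if key in seen:
                raise MappingSpecError(f"duplicate target object name {name} (also maps {seen[key]})")
            seen[key] = m.native_name
        if taxonomy is not None:
            for m in self.mappings:
                node = resolve_path(taxonomy, m.taxonomy_path)
                if node.level != 4:
                    raise MappingSpecError(
                        f"{m.object_name.name}: taxonomy path {'/'.join(m.taxonomy_path)} "
                        f"resolves to a level-{node.level} node, not an object"
                    )

    def to_dict(self) -> dict:
        return {
            "cohort_code": self.cohort_code.upper(),
            "spec_version": self.spec_version,
            "id_column": self.id_column,
            "mappings": [
                {
                    "native_name": m.native_name,
                    "object_name": m.object_name.name,
                    "modality": m.object_name.modality,
                    "taxonomy_path": list(m.taxonomy_path),
                    "full_text": m.full_text,
                    "units": m.units,
                    "value_labels": m.value_labels.to_dict(),
                    "rules": [r.to_dict() for r in m.rules],
                    "diagnosed_exempt": m.diagnosed_exempt,
                    "annotations": m.annotations,
                }
                for m in self.mappings
            ],
        }

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)


def _labels_from_raw(raw: Mapping | None) -> ValueLabelMap:
    if not raw:
        return ValueLabelMap()
    return ValueLabelMap(
        entries=dict(raw.get("entries", {})),
        missing_codes=frozenset(raw.get("missing_codes", ())),
        nonresponse_codes=frozenset(raw.get("nonresponse_codes", ())),
    )


def load_mapping_spec(source: str | Path | Mapping) -> MappingSpec:
    """Load a mapping spec from YAML/JSON text, a path, or a parsed mapping.
    The layout is published as ``csurv/schemas/mapping_spec.schema.json``."""
    if isinstance(source, Mapping):
        doc: Any = dict(source)
    else:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        else:
            p = Path(source)
            text = p.read_text(encoding="utf-8") if ("\n" not in source and p.is_file()) else source
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "cohort_code" not in doc:
        raise MappingSpecError("mapping spec must be a mapping with a 'cohort_code' key")
    mappings = []
    for raw in doc.get("mappings", []):
        modality = raw.get("modality", "survey")
        obj = parse_object_name(
            raw["object_name"], modality, diagnosed_exempt=bool(raw.get("diagnosed_exempt"))
        )
        mappings.append(
            VariableMapping(
                native_name=str(raw["native_name"]),
                object_name=obj,
                taxonomy_path=tuple(raw.get("taxonomy_path", ())),
                full_text=raw.get("full_text", ""),
                units=raw.get("units", ""),
                value_labels=_labels_from_raw(raw.get("value_labels")),
                rules=[RecodeRule(r["kind"], r.get("params", {})) for r in raw.get("rules", [])],
                diagnosed_exempt=bool(raw.get("diagnosed_exempt")),
                annotations=raw.get("annotations", ""),
            )
        )
    spec = MappingSpec(
        cohort_code=str(doc["cohort_code"]),
        spec_version=str(doc.get("spec_version", "1")),
        id_column=str(doc.get("id_column", ID_COLUMN)),
        mappings=mappings,
    )
    spec.validate()
    return spec


@dataclass
class DictionaryEntry:
    """One data-dictionary row: everything the variable name cannot say."""

    object_name: str
    taxonomy_path: NodePath
    full_text: str
    units: str
    value_labels: ValueLabelMap
    native_value_labels: ValueLabelMap
    missing_note: str
    serial: int
    wave: int
    native_name: str
    modality: str
    diagnosed: bool
    annotations: str = ""

    def to_dict(self) -> dict:
        return {
            "object_name": self.object_name,
            "theme": self.taxonomy_path[0] if len(self.taxonomy_path) > 0 else "",
            "domain": self.taxonomy_path[1] if len(self.taxonomy_path) > 1 else "",
            "family": self.taxonomy_path[2] if len(self.taxonomy_path) > 2 else "",
            "object_label": self.taxonomy_path[3] if len(self.taxonomy_path) > 3 else "",
            "full_text": self.full_text,
            "units": self.units,
            "value_labels": self.value_labels.to_dict(),
            "native_value_labels": self.native_value_labels.to_dict(),
            "missing_note": self.missing_note,
            "serial": self.serial,
            "wave": self.wave,
            "native_name": self.native_name,
            "modality": self.modality,
            "diagnosed": self.diagnosed,
            "annotations": self.annotations,
        }


@dataclass
class CuratedDataset:
    """Curated table + dictionary + curation report for one cohort."""

    cohort_code: str
    table: pd.DataFrame
    dictionary: list[DictionaryEntry]
    report: dict = field(default_factory=dict)


def apply_mapping(
    native_table: pd.DataFrame, spec: MappingSpec, taxonomy: Taxonomy
) -> CuratedDataset:
    """Execute a mapping spec against a native table.

    Validation (grammar, duplicate targets, taxonomy paths, presence of every
    native variable) happens before any data is touched; missing native
    variables are collected and reported together.  Mapped columns are
    recoded and renamed; unmapped native columns are excluded from the
    curated output but listed in the report so nothing silently disappears.
    """
    spec.validate(taxonomy)
    if spec.id_column not in native_table.columns:
        raise CurationError(f"participant-identifier column {spec.id_column!r} not in native table")
    absent = [m.native_name for m in spec.mappings if m.native_name not in native_table.columns]
    if absent:
        raise CurationError(
            f"{len(absent)} mapped native variable(s) absent from the native table: {absent}"
        )
    ids = native_table[spec.id_column]
    if ids.duplicated().any():
        raise IntegrityError(f"duplicate participant identifiers in {spec.id_column!r}")

    curated = pd.DataFrame({ID_COLUMN: ids.to_numpy()})
    dictionary: list[DictionaryEntry] = []
    cells_recoded = 0
    for m in spec.mappings:
        result = apply_conventions(native_table[m.native_name], m.value_labels, m.rules)
        name = m.object_name.name
        curated[name] = result.values.to_numpy()
        cells_recoded += sum(result.audit.values())
        dictionary.append(
            DictionaryEntry(
                object_name=name,
                taxonomy_path=tuple(m.taxonomy_path),
                full_text=m.full_text,
                units=m.units,
                value_labels=result.label_map,
                native_value_labels=result.native_label_map,
                missing_note=_MISSING_NOTE,
                serial=m.object_name.serial,
                wave=m.object_name.wave,
                native_name=m.native_name,
                modality=m.object_name.modality,
                diagnosed=m.object_name.diagnosed,
                annotations=m.annotations,
            )
        )

    mapped_natives = {m.native_name for m in spec.mappings}
    unmapped = [
        c for c in native_table.columns if c != spec.id_column and c not in mapped_natives
    ]
    report = {
        "cohort_code": spec.cohort_code.upper(),
        "rows": int(len(native_table)),
        "variables_mapped": len(spec.mappings),
        "variables_unmapped": len(unmapped),
        "unmapped_native_variables": unmapped,
        "cells_recoded": int(cells_recoded),
    }
    return CuratedDataset(
        cohort_code=spec.cohort_code.upper(),
        table=curated,
        dictionary=dictionary,
        report=report,
    )


# ---------------------------------------------------------------------------
# dictionary rendering
# ---------------------------------------------------------------------------

_DICT_COLUMNS = [
    "object_name", "theme", "domain", "family", "object_label", "full_text",
    "units", "value_labels", "native_value_labels", "missing_note",
    "serial", "wave", "native_name", "modality", "diagnosed", "annotations",
]


def build_dictionary(dataset: CuratedDataset) -> pd.DataFrame:
    """Render the dictionary as a flat table, one row per curated column, in
    deterministic (table) column order.  Label maps are JSON-encoded in the
    CSV rendering; :func:`write_curated` also emits a structured JSON form."""
    rows = []
    for entry in dataset.dictionary:
        d = entry.to_dict()
        d["value_labels"] = json.dumps(d["value_labels"], sort_keys=True)
        d["native_value_labels"] = json.dumps(d["native_value_labels"], sort_keys=True)
        rows.append(d)
    return pd.DataFrame(rows, columns=_DICT_COLUMNS)


def validate_curated(dataset: CuratedDataset, taxonomy: Taxonomy) -> list[str]:
    """Conformance check; returns violations (empty = conformant).

    Checks every column name against the grammar, one dictionary entry per
    column (and vice versa), every dictionary path against the taxonomy
    (must resolve to a level-4 object), and row-count consistency with the
    report.
    """
    violations: list[str] = []
    cols = [c for c in dataset.table.columns if c != ID_COLUMN]
    if ID_COLUMN not in dataset.table.columns:
        violations.append(f"curated table lacks the {ID_COLUMN!r} column")
    elif dataset.table[ID_COLUMN].duplicated().any():
        violations.append("duplicate participant identifiers")

    by_name = {e.object_name: e for e in dataset.dictionary}
    modalities = {e.object_name: e.modality for e in dataset.dictionary}
    for col in cols:
        try:
            parse_object_name(col, modalities.get(col, "survey"))
        except naming.NamingError as exc:
            violations.append(f"column {col!r}: grammar violation: {exc}")
        except Exception as exc:  # pragma: no cover - defensive
            violations.append(f"column {col!r}: {exc}")
        if col not in by_name:
            violations.append(f"column {col!r} has no dictionary entry")
    for entry in dataset.dictionary:
        if entry.object_name not in cols:
            violations.append(f"dictionary entry {entry.object_name!r} has no table column")
        try:
            node = resolve_path(taxonomy, entry.taxonomy_path)
        except Exception as exc:
            violations.append(f"{entry.object_name}: taxonomy path does not resolve: {exc}")
        else:
            if node.level != 4:
                violations.append(
                    f"{entry.object_name}: taxonomy path resolves to a level-{node.level} "
                    f"node, not a level-4 object"
                )
    if "rows" in dataset.report and dataset.report["rows"] != len(dataset.table):
        violations.append(
            f"report says {dataset.report['rows']} rows, table has {len(dataset.table)}"
        )
    return violations


# ---------------------------------------------------------------------------
# CSV boundary
# ---------------------------------------------------------------------------

def write_curated(dataset: CuratedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write ``curated.csv``, ``dictionary.csv``, ``dictionary.json`` and
    ``report.json`` into *outdir*; returns the paths.  Deterministic: equal
    datasets produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "curated": outdir / "curated.csv",
        "dictionary_csv": outdir / "dictionary.csv",
        "dictionary_json": outdir / "dictionary.json",
        "report": outdir / "report.json",
    }
    dataset.table.to_csv(paths["curated"], index=False, na_rep=MISSING_TOKEN, lineterminator="\n")
    build_dictionary(dataset).to_csv(paths["dictionary_csv"], index=False, lineterminator="\n")
    paths["dictionary_json"].write_text(
        json.dumps([e.to_dict() for e in dataset.dictionary], indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    paths["report"].write_text(
        json.dumps(dataset.report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def read_curated_csv(path: str | Path) -> pd.DataFrame:
    """Read a curated CSV: only the ``.`` token is missing (native-style
    markers such as NA or blank are data at this layer, not missingness)."""
    return pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False, dtype=object)


def read_native_csv(path: str | Path) -> pd.DataFrame:
    """Read a native CSV without interpreting any marker as missing: native
    missing codes (including blank cells) must reach the recoder as values."""
    return pd.read_csv(path, keep_default_na=False, na_values=[], dtype=object)
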
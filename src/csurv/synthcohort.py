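"""Seeded generator of messy native-style cohort datasets with known truth.

Real cohort data live behind data-access committees, so the toolkit is
exercised against synthetic cohorts that emulate what the landscape of
population studies actually looks like: project-specific variable names
(snake_case, CamelCase, or cryptic positional codes), imperial units on
anthropometry, per-cohort native missing codes (-9, -99, blank, "NA"),
labelled informative non-response ("don't know", "prefer not to answer"),
genuine missingness, and repeated measures within and between waves.

Every generated table comes with a :class:`TruthManifest`: the mapping spec
that correctly curates it plus the expected curated values, computed cell by
cell during generation.  Curation is therefore testable end to end with an
exact oracle — apply the manifest's spec and compare against the truth.

Randomness is numpy's PCG64 generator seeded from the config; identical
config + seed gives identical output across runs and platforms (categorical
and indicator draws go through integer/uniform paths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .curate import (
    CuratedDataset,
    DictionaryEntry,
    ID_COLUMN,
    MappingSpec,
    VariableMapping,
    apply_mapping,
)
from .errors import SynthConfigError
from .explorer import FilterStep, FunnelResult, FunnelStepResult, HarmonisedVariable
from .naming import ObjectName
from .recode import MISSING, RecodeRule, ValueLabelMap, _code_key, conversion_factor

__all__ = [
    "GENERATOR_ID",
    "VariableBlueprint",
    "SynthConfig",
    "TruthManifest",
    "generate_native_cohort",
    "default_blueprints",
    "table1_blueprints",
    "PlantedFunnel",
    "plant_funnel",
]

GENERATOR_ID = "numpy-PCG64-v1"

NAME_STYLES = ("snake", "camel", "cryptic")

#: Native missing code by naming style: different cohorts mark absence
#: differently, and the recoder must cope with all of them.
STYLE_MISSING_CODES: dict[str, Any] = {"snake": -9, "camel": -99, "cryptic": ""}

_STYLE_ID_COLUMNS = {"snake": "participant_id", "camel": "ParticipantID", "cryptic": "pid"}


@dataclass(frozen=True)
class VariableBlueprint:
    """Recipe for one synthetic variable.

    ``key`` seeds the idiosyncratic native name; ``measurement`` is the
    curated abbreviation.  ``kind`` is ``categorical`` (codes drawn uniformly
    from ``categories``), ``continuous`` (Gaussian, rounded to ``decimals``),
    or ``score`` (uniform integer in [score_min, score_max]).
    ``serial_repeats`` = 0 generates one unrepeated column (serial 0);
    k >= 1 generates serials 1..k per wave.
    """

    key: str
    measurement: str
    taxonomy_path: tuple[str, ...]
    kind: str = "continuous"
    name_style: str = "snake"
    modality: str = "survey"
    categories: Mapping[Any, str] = field(default_factory=dict)
    gender: bool = False
    mean: float = 0.0
    sd: float = 1.0
    decimals: int = 2
    score_min: int = 0
    score_max: int = 10
    native_unit: str | None = None
    curated_unit: str | None = None
    missing_rate: float = 0.05
    nonresponse_rate: float = 0.0
    nonresponse: Mapping[Any, str] = field(default_factory=dict)
    missing_code: Any = None  # None -> the style default
    serial_repeats: int = 0
    item: int | None = None
    full_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", dict(self.categories))
        object.__setattr__(self, "nonresponse", dict(self.nonresponse))
        if self.kind not in ("categorical", "continuous", "score"):
            raise SynthConfigError(f"{self.key}: unknown kind {self.kind!r}")
        if self.name_style not in NAME_STYLES:
            raise SynthConfigError(f"{self.key}: unknown name style {self.name_style!r}")
        if self.kind == "categorical" and not self.categories:
            raise SynthConfigError(f"{self.key}: categorical blueprint needs categories")
        if not (0 <= self.missing_rate < 1 and 0 <= self.nonresponse_rate < 1):
            raise SynthConfigError(f"{self.key}: rates must lie in [0, 1)")
        if self.missing_rate + self.nonresponse_rate >= 1:
            raise SynthConfigError(f"{self.key}: missing_rate + nonresponse_rate must be < 1")
        if self.nonresponse_rate > 0 and not self.nonresponse:
            raise SynthConfigError(f"{self.key}: nonresponse_rate > 0 needs labelled codes")
        if self.sd <= 0:
            raise SynthConfigError(f"{self.key}: sd must be positive")
        if self.score_max < self.score_min:
            raise SynthConfigError(f"{self.key}: score_max < score_min")
        if self.serial_repeats < 0:
            raise SynthConfigError(f"{self.key}: serial_repeats must be >= 0")
        if (self.native_unit is None) != (self.curated_unit is None):
            raise SynthConfigError(f"{self.key}: native_unit and curated_unit go together")
        if self.native_unit is not None:
            conversion_factor(self.native_unit, self.curated_unit)  # raises if unknown

    @property
    def effective_missing_code(self) -> Any:
        return STYLE_MISSING_CODES[self.name_style] if self.missing_code is None else self.missing_code

    def serials(self) -> list[int]:
        return [0] if self.serial_repeats == 0 else list(range(1, self.serial_repeats + 1))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    cohort_code: str
    n_participants: int
    variables: tuple[VariableBlueprint, ...]
    waves: int = 1
    seed: int = 0
    id_column: str = "participant_id"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        code = self.cohort_code
        if not (len(code) == 3 and code.isalpha()):
            raise SynthConfigError(f"cohort_code must be 3 alphabetic characters, got {code!r}")
        object.__setattr__(self, "cohort_code", code.upper())
        if self.n_participants < 0:
            raise SynthConfigError("n_participants must be non-negative")
        if self.waves < 1:
            raise SynthConfigError("waves must be >= 1")
        if not self.variables:
            raise SynthConfigError("at least one variable blueprint is required")
        keys = [v.key for v in self.variables]
        if len(set(keys)) != len(keys):
            raise SynthConfigError("blueprint keys must be unique")

    def to_dict(self) -> dict:
        return {
            "cohort_code": self.cohort_code,
            "n_participants": self.n_participants,
            "waves": self.waves,
            "seed": self.seed,
            "id_column": self.id_column,
            "variables": [v.key for v in self.variables],
        }


@dataclass
class TruthManifest:
    """Ground truth accompanying a generated native table."""

    spec: MappingSpec
    expected: pd.DataFrame  # curated truth: id column + one column per object
    config: SynthConfig
    generator: str = GENERATOR_ID


def _native_name(bp: VariableBlueprint, position: int, serial: int, wave: int, waves: int) -> str:
    """Idiosyncratic native column name, deterministic in the blueprint."""
    if bp.name_style == "snake":
        parts = [bp.key]
        if bp.serial_repeats:
            parts.append(f"rep{serial}")
        if waves > 1:
            parts.append(f"w{wave}")
        return "_".join(parts)
    if bp.name_style == "camel":
        camel = "".join(w.capitalize() for w in bp.key.split("_"))
        if bp.serial_repeats:
            camel += f"R{serial}"
        if waves > 1:
            camel += f"Wave{wave}"
        return camel
    # cryptic: positional code in the cohort's internal numbering
    return f"v{position:02d}_{serial}_{wave}"


def _curate_value(bp: VariableBlueprint, native_value: Any) -> Any:
    if bp.gender:
        # label-driven: find which native code means female/male
        lab = str(bp.categories.get(native_value, "")).casefold()
        if lab in ("female", "f", "woman"):
            return 2
        if lab in ("male", "m", "man"):
            return 1
        return native_value
    if bp.native_unit is not None:
        return float(native_value) * conversion_factor(bp.native_unit, bp.curated_unit)
    return native_value


def _draw_column(bp: VariableBlueprint, n: int, rng: np.random.Generator):
    """Draw one column; returns (native_values, curated_truth) lists."""
    u = rng.random(n)
    miss = u < bp.missing_rate
    nonresp = (~miss) & (u < bp.missing_rate + bp.nonresponse_rate)

    if bp.kind == "categorical":
        codes = list(bp.categories.keys())
        base = [codes[i] for i in rng.integers(0, len(codes), n)]
    elif bp.kind == "score":
        base = [int(x) for x in rng.integers(bp.score_min, bp.score_max + 1, n)]
    else:
        base = [float(x) for x in np.round(rng.normal(bp.mean, bp.sd, n), bp.decimals)]

    nr_codes = list(bp.nonresponse.keys())
    nr_pick = rng.integers(0, max(len(nr_codes), 1), n)

    reserved = {_code_key(bp.effective_missing_code)} | {_code_key(c) for c in nr_codes}
    native: list[Any] = []
    curated: list[Any] = []
    for i in range(n):
        if miss[i]:
            native.append(bp.effective_missing_code)
            curated.append(MISSING)
        elif nonresp[i]:
            code = nr_codes[nr_pick[i]]
            native.append(code)
            curated.append(code)  # informative non-response stays a value
        else:
            if _code_key(base[i]) in reserved:
                raise SynthConfigError(
                    f"{bp.key}: drawn value {base[i]!r} collides with a missing/non-response "
                    f"code; choose codes outside the variable's support"
                )
            native.append(base[i])
            curated.append(_curate_value(bp, base[i]))
    return native, curated


def _blueprint_mapping(
    bp: VariableBlueprint, cohort_code: str, native_name: str, serial: int, wave: int
) -> VariableMapping:
    entries = dict(bp.categories)
    entries.update(bp.nonresponse)
    labels = ValueLabelMap(
        entries=entries,
        missing_codes=frozenset({bp.effective_missing_code}),
        nonresponse_codes=frozenset(bp.nonresponse.keys()),
    )
    rules: list[RecodeRule] = [RecodeRule("missing")]
    if bp.gender:
        rules.append(RecodeRule("gender"))
    if bp.native_unit is not None:
        rules.append(
            RecodeRule(
                "unit_conversion",
                {"source_unit": bp.native_unit, "target_unit": bp.curated_unit},
            )
        )
    diagnosed = bp.measurement.upper().endswith("DX")
    obj = ObjectName(
        cohort=cohort_code,
        measurement=bp.measurement,
        serial=serial,
        wave=wave,
        item=bp.item,
        modality=bp.modality,
        diagnosed=diagnosed,
    )
    return VariableMapping(
        native_name=native_name,
        object_name=obj,
        taxonomy_path=bp.taxonomy_path,
        full_text=bp.full_text,
        units=bp.curated_unit or "",
        value_labels=labels,
        rules=rules,
    )


def generate_native_cohort(config: SynthConfig) -> tuple[pd.DataFrame, TruthManifest]:
    """Generate a messy native table and the manifest that curates it.

    Deterministic in ``config.seed``; columns are laid out wide (one row per
    participant), ordered blueprint x wave x serial.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i + 1:06d}" for i in range(n)]

    native = pd.DataFrame({config.id_column: ids}, dtype=object)
    expected = pd.DataFrame({ID_COLUMN: ids}, dtype=object)
    mappings: list[VariableMapping] = []

    for pos, bp in enumerate(config.variables, start=1):
        for wave in range(1, config.waves + 1):
            for serial in bp.serials():
                col = _native_name(bp, pos, serial, wave, config.waves)
                values, truth = _draw_column(bp, n, rng)
                native[col] = pd.Series(values, dtype=object)
                mapping = _blueprint_mapping(bp, config.cohort_code, col, serial, wave)
                expected[mapping.object_name.name] = pd.Series(truth, dtype=object)
                mappings.append(mapping)

    spec = MappingSpec(
        cohort_code=config.cohort_code,
        spec_version="1",
        id_column=config.id_column,
        mappings=mappings,
    )
    spec.validate()
    return native, TruthManifest(spec=spec, expected=expected, config=config)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_blueprints() -> tuple[VariableBlueprint, ...]:
    """A realistic survey battery for an ageing cohort.

    Mix of naming styles, an imperial-unit pair (height in inches, weight in
    pounds), labelled non-response on self-report items, and missingness
    rates rising from administrative items (~1-3%) through survey items
    (~5-10%) to burdensome tasks (~15%), as is typical of such studies.
    Taxonomy paths resolve against the shipped reference taxonomy.
    """
    return (
        VariableBlueprint(
            key="yob", measurement="YOB", kind="score", score_min=1935, score_max=1970,
            name_style="snake", missing_rate=0.01,
            taxonomy_path=("Sociodemographic", "Demographic indicators", "Age", "Year of birth"),
            full_text="Year of birth",
        ),
        VariableBlueprint(
            key="age", measurement="AGE", kind="continuous", mean=62.0, sd=9.0, decimals=0,
            name_style="snake", missing_rate=0.01,
            taxonomy_path=("Sociodemographic", "Demographic indicators", "Age", "Age"),
            full_text="Age at assessment (years)",
        ),
        VariableBlueprint(
            key="sex", measurement="SEX", kind="categorical",
            categories={0: "Male", 1: "Female"}, gender=True,
            nonresponse={9: "Prefer not to answer"}, nonresponse_rate=0.01,
            name_style="camel", missing_rate=0.01,
            taxonomy_path=("Sociodemographic", "Demographic indicators", "Gender", "Sex"),
            full_text="Sex",
        ),
        VariableBlueprint(
            key="edu_years", measurement="EDUYRS", kind="score", score_min=0, score_max=20,
            name_style="snake", missing_rate=0.03,
            taxonomy_path=("Sociodemographic", "Education", "Educational experience",
                           "Years education"),
            full_text="Years of full-time education completed",
        ),
        VariableBlueprint(
            key="smoking", measurement="SMOKSTAT", kind="categorical",
            categories={0: "Never", 1: "Former", 2: "Current"},
            nonresponse={8: "Don't know"}, nonresponse_rate=0.03,
            name_style="camel", missing_rate=0.08,
            taxonomy_path=("Lifestyle behaviour", "Substance use", "Tobacco", "Smoking status"),
            full_text="Smoking status",
        ),
        VariableBlueprint(
            key="alcohol_units", measurement="ALCUNITSWK", kind="score",
            score_min=0, score_max=40,
            nonresponse={98: "Don't know"}, nonresponse_rate=0.02,
            name_style="snake", missing_rate=0.10,
            taxonomy_path=("Lifestyle behaviour", "Substance use", "Alcohol",
                           "Alcohol units/wk"),
            full_text="Units of alcohol in a typical week",
        ),
        VariableBlueprint(
            key="height", measurement="HEIGHT", kind="continuous", mean=66.0, sd=4.0,
            decimals=1, native_unit="inch", curated_unit="cm",
            name_style="snake", missing_rate=0.05,
            taxonomy_path=("Physical examination", "Musculo-skeletal", "Structural", "Height"),
            full_text="Standing height (recorded in inches)",
        ),
        VariableBlueprint(
            key="weight", measurement="WEIGHT", kind="continuous", mean=165.0, sd=30.0,
            decimals=1, native_unit="pound", curated_unit="kg",
            name_style="snake", missing_rate=0.05,
            taxonomy_path=("Physical examination", "Musculo-skeletal", "Structural", "Weight"),
            full_text="Body weight (recorded in pounds)",
        ),
        VariableBlueprint(
            key="dep_scale", measurement="DEPSCALE", kind="score", score_min=0, score_max=27,
            name_style="camel", missing_rate=0.12,
            taxonomy_path=("Psychological status", "Self-report mental health", "Depression",
                           "Depression scale"),
            full_text="Depression symptom scale total score",
        ),
        VariableBlueprint(
            key="reaction_time", measurement="REACTIME", kind="continuous", mean=450.0,
            sd=80.0, decimals=0, name_style="cryptic", missing_rate=0.15,
            taxonomy_path=("Cognitive status", "Processing speed", "Task response time",
                           "Reaction time task"),
            full_text="Mean reaction time over correct trials (ms)",
        ),
    )


_TABLE1_MEASUREMENTS: dict[str, tuple[str, str]] = {
    # object label -> (measurement abbreviation, modality)
    "Year of birth": ("YOB", "survey"),
    "Age": ("AGE", "survey"),
    "Sex": ("SEX", "survey"),
    "Years education": ("EDUYRS", "survey"),
    "Dementia Diagnosis": ("DEMDX", "survey"),
    "PD Diagnosis": ("PDDX", "survey"),
    "Episodic disorders": ("EPIDIS", "survey"),
    "Other neurological disorders": ("OTHNEURO", "survey"),
    "CVD": ("CVD", "survey"),
    "Stroke": ("STROKE", "survey"),
    "MCI": ("MCI", "survey"),
    "Prescription medications": ("MEDSRX", "survey"),
    "Family history dementia": ("FAMDEM", "survey"),
    "Family history PD": ("FAMPD", "survey"),
    "Family history stroke": ("FAMSTROKE", "survey"),
    "Depression scale": ("DEPSCALE", "survey"),
    "PTSD": ("PTSD", "survey"),
    "Immediate recall": ("IMMRECALL", "survey"),
    "Delayed recall": ("DELRECALL", "survey"),
    "Executive function task": ("EXECFUNC", "survey"),
    "Reaction time task": ("REACTIME", "survey"),
    "Subjective memory complaint": ("SUBJMEM", "survey"),
    "Cognitive impairment": ("COGIMP", "survey"),
    "Alcohol units/wk": ("ALCUNITSWK", "survey"),
    "Smoking status": ("SMOKSTAT", "survey"),
    "BMI": ("BMI", "survey"),
    "BP systolic": ("BPSYS", "survey"),
    "BP Diastolic": ("BPDIA", "survey"),
    "MRI images": ("MRIIMG", "imaging"),
    "CRP": ("CRP", "omics"),
    "CSF Tau": ("CSFTAU", "omics"),
    "APOE": ("APOE", "omics"),
}


def table1_blueprints(taxonomy) -> tuple[VariableBlueprint, ...]:
    """One generic blueprint per object of the harmonised reference subset.

    Binary-ish clinical flags become yes/no categoricals, scales become
    scores, everything else a generic continuous measure; abbreviations come
    from a fixed per-object table (diagnosis objects end in DX).  Used to
    build a demonstration dataset whose dictionary covers the whole subset.
    """
    from .taxonomy import list_objects

    styles = ("snake", "camel", "cryptic")
    out = []
    for i, (path, node) in enumerate(list_objects(taxonomy)):
        label = node.object_label or node.label
        meas, modality = _TABLE1_MEASUREMENTS[label]
        key = "".join(c if c.isalnum() else "_" for c in label.lower())
        common = dict(
            key=key,
            measurement=meas,
            modality=modality,
            taxonomy_path=path,
            name_style=styles[i % 3],
            missing_rate=0.05,
            full_text=label,
        )
        if label == "Sex":
            out.append(
                VariableBlueprint(
                    kind="categorical", categories={0: "Male", 1: "Female"}, gender=True,
                    **common,
                )
            )
        elif meas.endswith("DX") or label in (
            "CVD", "Stroke", "MCI", "Episodic disorders", "Other neurological disorders",
            "Family history dementia", "Family history PD", "Family history stroke",
            "PTSD", "Subjective memory complaint", "Cognitive impairment", "APOE",
        ):
            out.append(
                VariableBlueprint(kind="categorical", categories={0: "No", 1: "Yes"}, **common)
            )
        elif label in ("Year of birth",):
            out.append(VariableBlueprint(kind="score", score_min=1935, score_max=1970, **common))
        elif label in ("Depression scale", "Immediate recall", "Delayed recall",
                       "Years education", "Alcohol units/wk", "Prescription medications"):
            out.append(VariableBlueprint(kind="score", score_min=0, score_max=20, **common))
        else:
            out.append(VariableBlueprint(kind="continuous", mean=50.0, sd=10.0, **common))
    return tuple(out)


# ---------------------------------------------------------------------------
# planted funnels
# ---------------------------------------------------------------------------

@dataclass
class PlantedFunnel:
    """Cohorts with independently drawn filter indicators and the exact
    funnel counts tallied from the drawn values (not from expectations)."""

    cohorts: list[CuratedDataset]
    variables: list[HarmonisedVariable]
    steps: list[FilterStep]
    expected: FunnelResult


def plant_funnel(
    cohort_codes: Sequence[str],
    n_participants: int,
    pass_rates: Sequence[float],
    seed: int,
    *,
    all_missing_steps: Sequence[int] = (),
) -> PlantedFunnel:
    """Generate curated cohorts where each participant independently passes
    filter k with probability ``pass_rates[k]``, plus the exact expected
    funnel counts (tallies of the drawn indicator conjunctions).

    ``all_missing_steps`` lists step indices whose variable is generated
    all-missing (its tally, and every later one, is 0).
    """
    if not pass_rates:
        raise SynthConfigError("at least one pass rate is required")
    for r in pass_rates:
        if not (0 < r <= 1):
            raise SynthConfigError(f"pass rates must lie in (0, 1], got {r}")
    rng = np.random.default_rng(seed)
    k = len(pass_rates)

    variables = [
        HarmonisedVariable(
            label=f"Filter {j + 1}",
            per_cohort_object={c.upper(): f"{c.upper()}_FLT{j + 1}_0_1" for c in cohort_codes},
        )
        for j in range(k)
    ]
    steps = [
        FilterStep(variable=variables[j], op="eq", value=1, description=f"Filter {j + 1} = 1")
        for j in range(k)
    ]

    cohorts: list[CuratedDataset] = []
    base: dict[str, int] = {}
    tallies: list[dict[str, int]] = [dict() for _ in range(k)]
    for code in cohort_codes:
        code = code.upper()
        ids = [f"P{i + 1:06d}" for i in range(n_participants)]
        table = pd.DataFrame({ID_COLUMN: ids}, dtype=object)
        alive = np.ones(n_participants, dtype=bool)
        dictionary: list[DictionaryEntry] = []
        for j, rate in enumerate(pass_rates):
            if j in all_missing_steps:
                col_vals = pd.Series([MISSING] * n_participants, dtype=object)
                indicator = np.zeros(n_participants, dtype=bool)
            else:
                passed = rng.random(n_participants) < rate
                col_vals = pd.Series([int(p) for p in passed], dtype=object)
                indicator = passed
            name = f"{code}_FLT{j + 1}_0_1"
            table[name] = col_vals
            alive = alive & indicator
            tallies[j][code] = int(alive.sum())
            dictionary.append(
                DictionaryEntry(
                    object_name=name,
                    taxonomy_path=(),
                    full_text=f"Planted filter indicator {j + 1} (synthetic)",
                    units="",
                    value_labels=ValueLabelMap(entries={0: "Fail", 1: "Pass"}),
                    native_value_labels=ValueLabelMap(entries={0: "Fail", 1: "Pass"}),
                    missing_note="missing (absence of recorded data) serialised as '.'",
                    serial=0,
                    wave=1,
                    native_name=f"flt{j + 1}",
                    modality="survey",
                    diagnosed=False,
                )
            )
        base[code] = n_participants
        cohorts.append(
            CuratedDataset(
                cohort_code=code,
                table=table,
                dictionary=dictionary,
                report={"rows": n_participants, "variables_mapped": k,
                        "variables_unmapped": 0, "cells_recoded": 0},
            )
        )

    expected = FunnelResult(base=base, base_pooled=sum(base.values()))
    for j in range(k):
        expected.steps.append(
            FunnelStepResult(
                step=steps[j],
                per_cohort=dict(tallies[j]),
                pooled=sum(tallies[j].values()),
            )
        )
    return PlantedFunnel(cohorts=cohorts, variables=variables, steps=steps, expected=expected)


def curated_from_config(config: SynthConfig, taxonomy) -> tuple[CuratedDataset, TruthManifest]:
    """Convenience: generate a native cohort and curate it with its own truth
    spec in one step."""
    native, manifest = generate_native_cohort(config)
    dataset = apply_mapping(native, manifest.spec, taxonomy)
    return dataset, manifest
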
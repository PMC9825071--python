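"""Native -> curated pipeline and data-dictionary generation."""

import json

import pandas as pd
import pytest

from csurv.curate import (
    CuratedDataset,
    MappingSpec,
    VariableMapping,
    apply_mapping,
    build_dictionary,
    load_mapping_spec,
    read_curated_csv,
    validate_curated,
    write_curated,
)
from csurv.errors import CurationError, MappingSpecError
from csurv.naming import ObjectName
from csurv.recode import MISSING, RecodeRule, ValueLabelMap, is_missing
from csurv.synthcohort import SynthConfig, generate_native_cohort, table1_blueprints
from csurv.taxonomy import reference_taxonomy


def _equal_with_missing(a, b) -> bool:
    if is_missing(a) or is_missing(b):
        return is_missing(a) and is_missing(b)
    return a == b


GENDER_SPEC = MappingSpec(
    cohort_code="GEN",
    id_column="pid",
    mappings=[
        VariableMapping(
            native_name="sex",
            object_name=ObjectName(cohort="GEN", measurement="SEX", serial=0, wave=1),
            taxonomy_path=("Sociodemographic", "Demographic indicators", "Gender", "Sex"),
            value_labels=ValueLabelMap(entries={0: "Male", 1: "Female"}),
            rules=[RecodeRule("gender")],
        )
    ],
)


class TestApplyMapping:
    def test_truth_manifest_round_trip_exact(self, small_cohort, ref_tax):
        native, manifest = small_cohort
        dataset = apply_mapping(native, manifest.spec, ref_tax)
        assert list(dataset.table.columns) == list(manifest.expected.columns)
        for col in manifest.expected.columns:
            got, exp = dataset.table[col], manifest.expected[col]
            assert all(_equal_with_missing(g, e) for g, e in zip(got, exp)), col

    def test_empty_spec_yields_id_only(self, ref_tax):
        native = pd.DataFrame({"id": [1, 2], "junk": [3, 4]})
        ds = apply_mapping(native, MappingSpec(cohort_code="ABC"), ref_tax)
        assert list(ds.table.columns) == ["id"]
        assert ds.report["variables_mapped"] == 0
        assert ds.report["unmapped_native_variables"] == ["junk"]

    def test_gender_convention_applied(self, ref_tax):
        native = pd.DataFrame({"pid": ["a", "b"], "sex": [0, 1]})
        ds = apply_mapping(native, GENDER_SPEC, ref_tax)
        assert list(ds.table["GEN_SEX_0_1"]) == [1, 2]

    def test_absent_native_variables_collected(self, ref_tax):
        native = pd.DataFrame({"pid": ["a"]})
        with pytest.raises(CurationError, match="sex"):
            apply_mapping(native, GENDER_SPEC, ref_tax)

    def test_duplicate_target_names_rejected(self, ref_tax):
        m = GENDER_SPEC.mappings[0]
        spec = MappingSpec(cohort_code="GEN", id_column="pid", mappings=[m, m])
        with pytest.raises(MappingSpecError, match="duplicate"):
            apply_mapping(pd.DataFrame({"pid": [], "sex": []}), spec, ref_tax)

    def test_taxonomy_path_must_reach_an_object(self, ref_tax):
        m = GENDER_SPEC.mappings[0]
        bad = VariableMapping(
            native_name=m.native_name, object_name=m.object_name,
            taxonomy_path=("Sociodemographic", "Demographic indicators", "Gender"),
            value_labels=m.value_labels, rules=m.rules,
        )
        spec = MappingSpec(cohort_code="GEN", id_column="pid", mappings=[bad])
        with pytest.raises(MappingSpecError, match="level-3"):
            apply_mapping(pd.DataFrame({"pid": [1], "sex": [0]}), spec, ref_tax)

    def test_report_arithmetic(self, small_cohort, ref_tax):
        native, manifest = small_cohort
        ds = apply_mapping(native, manifest.spec, ref_tax)
        n_native = len(native.columns) - 1  # id column excluded
        assert ds.report["variables_mapped"] + ds.report["variables_unmapped"] == n_native


@pytest.fixture(scope="module")
def table1_dataset(t1_tax):
    """Demo dataset covering the whole 32-object harmonised subset."""
    config = SynthConfig(
        cohort_code="DEM", n_participants=50,
        variables=table1_blueprints(t1_tax), seed=5,
    )
    native, manifest = generate_native_cohort(config)
    return apply_mapping(native, manifest.spec, t1_tax)


class TestDictionary:
    def test_full_harmonised_battery_has_32_entries(self, table1_dataset):
        assert len(table1_dataset.dictionary) == 32
        assert len(build_dictionary(table1_dataset)) == 32

    def test_diagnosed_provenance_carried(self, table1_dataset):
        entry = next(e for e in table1_dataset.dictionary if "DEMDX" in e.object_name)
        assert entry.diagnosed is True

    def test_entries_carry_native_and_curated_labels(self, table1_dataset):
        entry = next(e for e in table1_dataset.dictionary if "SEX" in e.object_name)
        assert entry.native_value_labels.entries[0] == "Male"
        assert entry.value_labels.entries[2] == "Female"

    def test_single_entry_dictionary_round_trips(self, ref_tax, tmp_path):
        native = pd.DataFrame({"pid": ["a"], "sex": [1]})
        ds = apply_mapping(native, GENDER_SPEC, ref_tax)
        paths = write_curated(ds, tmp_path)
        df = pd.read_csv(paths["dictionary_csv"])
        assert len(df) == 1 and df.loc[0, "object_name"] == "GEN_SEX_0_1"
        doc = json.loads(paths["dictionary_json"].read_text())
        assert doc[0]["object_name"] == "GEN_SEX_0_1"
        assert doc[0]["theme"] == "Sociodemographic"


class TestValidateCurated:
    def test_pipeline_output_is_conformant(self, small_cohort, ref_tax):
        native, manifest = small_cohort
        ds = apply_mapping(native, manifest.spec, ref_tax)
        assert validate_curated(ds, ref_tax) == []

    def test_corrupted_column_name_reported(self, small_cohort, ref_tax):
        native, manifest = small_cohort
        ds = apply_mapping(native, manifest.spec, ref_tax)
        ds.table = ds.table.rename(columns={"GEN_AGE_0_1": "GEN_BAD"})
        violations = validate_curated(ds, ref_tax)
        assert any("GEN_BAD" in v and "grammar" in v for v in violations)

    def test_dictionary_path_to_family_reported(self, ref_tax):
        native = pd.DataFrame({"pid": ["a"], "sex": [1]})
        ds = apply_mapping(native, GENDER_SPEC, ref_tax)
        ds.dictionary[0].taxonomy_path = ("Sociodemographic", "Demographic indicators", "Gender")
        violations = validate_curated(ds, ref_tax)
        assert any("level-3" in v for v in violations)


class TestSerialisation:
    def test_curated_csv_uses_dot_for_missing(self, ref_tax, tmp_path):
        native = pd.DataFrame({"pid": ["a", "b"], "sex": [0, -9]})
        spec = load_mapping_spec(
            {
                "cohort_code": "GEN",
                "id_column": "pid",
                "mappings": [
                    {
                        "native_name": "sex",
                        "object_name": "GEN_SEX_0_1",
                        "taxonomy_path": ["Sociodemographic", "Demographic indicators",
                                          "Gender", "Sex"],
                        "value_labels": {"entries": {0: "Male", 1: "Female"},
                                         "missing_codes": [-9]},
                        "rules": [{"kind": "missing"}, {"kind": "gender"}],
                    }
                ],
            }
        )
        ds = apply_mapping(native, spec, ref_tax)
        paths = write_curated(ds, tmp_path)
        lines = paths["curated"].read_text().splitlines()
        assert lines[0] == "id,GEN_SEX_0_1"
        assert lines[2] == "b,."
        back = read_curated_csv(paths["curated"])
        assert is_missing(back["GEN_SEX_0_1"][1])

    def test_byte_identical_outputs_for_identical_inputs(self, small_cohort, ref_tax, tmp_path):
        native, manifest = small_cohort
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            write_curated(apply_mapping(native, manifest.spec, ref_tax), out)
        for name in ("curated.csv", "dictionary.csv", "dictionary.json", "report.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_mapping_spec_round_trips_through_yaml(self, small_cohort):
        _, manifest = small_cohort
        again = load_mapping_spec(manifest.spec.dumps())
        assert [m.object_name.name for m in again.mappings] == [
            m.object_name.name for m in manifest.spec.mappings
        ]
        assert again.id_column == manifest.spec.id_column
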
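{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://csurv.invalid/schemas/mapping_spec.schema.json",
  "title": "csurv mapping spec",
  "description": "Per-cohort declaration binding native variables to curated object names, taxonomy objects and recode rules. Grammar conformance of object names, uniqueness of targets and taxonomy-path resolution are enforced by the csurv loader.",
  "type": "object",
  "required": ["cohort_code", "mappings"],
  "properties": {
    "cohort_code": {"type": "string", "pattern": "^[A-Za-z]{3}$"},
    "spec_version": {"type": ["string", "number"]},
    "id_column": {"type": "string", "minLength": 1},
    "mappings": {
      "type": "array",
      "items": {"$ref": "#/$defs/variable_mapping"}
    }
  },
  "$defs": {
    "variable_mapping": {
      "type": "object",
      "required": ["native_name", "object_name"],
      "properties": {
        "native_name": {"type": "string", "minLength": 1},
        "object_name": {"type": "string", "minLength": 9},
        "modality": {"enum": ["survey", "imaging", "omics", "device"]},
        "taxonomy_path": {
          "type": "array",
          "items": {"type": "string"},
          "minItems": 4,
          "maxItems": 4
        },
        "full_text": {"type": "string"},
        "units": {"type": "string"},
        "value_labels": {"$ref": "#/$defs/value_label_map"},
        "rules": {"type": "array", "items": {"$ref": "#/$defs/recode_rule"}},
        "diagnosed_exempt": {"type": "boolean"},
        "annotations": {"type": "string"}
      },
      "additionalProperties": false
    },
    "value_label_map": {
      "type": "object",
      "properties": {
        "entries": {"type": "object"},
        "missing_codes": {"type": "array"},
        "nonresponse_codes": {"type": "array"}
      },
      "additionalProperties": false
    },
    "recode_rule": {
      "type": "object",
      "required": ["kind"],
      "properties": {
        "kind": {
          "enum": ["missing", "gender", "unit_conversion", "passthrough",
                   "custom_map", "nonresponse_remap"]
        },
        "params": {"type": "object"}
      },
      "additionalProperties": false
    }
  }
}
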
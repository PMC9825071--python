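{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://csurv.invalid/schemas/taxonomy.schema.json",
  "title": "csurv taxonomy document",
  "description": "Four-level acyclic taxonomy: themes (level 1) > domains > families > objects (level 4). Structural invariants beyond nesting depth (sibling label uniqueness case-insensitive, unique theme indices, provisional-stub rules) are enforced by the csurv loader.",
  "type": "object",
  "required": ["themes"],
  "properties": {
    "version": {"type": ["string", "number"]},
    "themes": {
      "type": "array",
      "items": {"$ref": "#/$defs/theme"}
    }
  },
  "$defs": {
    "theme": {
      "type": "object",
      "required": ["label"],
      "properties": {
        "index": {"type": "integer", "minimum": 1},
        "label": {"type": "string", "minLength": 1},
        "provisional": {"type": "boolean"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/domain"}}
      },
      "additionalProperties": false
    },
    "domain": {
      "type": "object",
      "required": ["label"],
      "properties": {
        "index": {"type": "integer", "minimum": 1},
        "label": {"type": "string", "minLength": 1},
        "provisional": {"type": "boolean"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/family"}}
      },
      "additionalProperties": false
    },
    "family": {
      "type": "object",
      "required": ["label"],
      "properties": {
        "index": {"type": "integer", "minimum": 1},
        "label": {"type": "string", "minLength": 1},
        "provisional": {"type": "boolean"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/object"}}
      },
      "additionalProperties": false
    },
    "object": {
      "type": "object",
      "required": ["label"],
      "properties": {
        "index": {"type": "integer", "minimum": 1},
        "label": {"type": "string", "minLength": 1},
        "object_label": {"type": "string", "minLength": 1},
        "provisional": {"type": "boolean"}
      },
      "additionalProperties": false
    }
  }
}
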
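{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/protoact/catalog.schema.json",
  "title": "Experimental-action catalog",
  "type": "object",
  "required": ["version", "actions"],
  "properties": {
    "version": {"type": ["string", "number"]},
    "actions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label", "provenance"],
        "properties": {
          "id": {"type": "string", "pattern": "^EXACT2_[0-9]{6}$"},
          "label": {"type": "string"},
          "definition": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}},
          "provenance": {"enum": ["legacy", "added_v2", "imported_obi"]},
          "essential": {"type": "array", "items": {"$ref": "#/definitions/kind"}},
          "optional": {"type": "array", "items": {"$ref": "#/definitions/kind"}},
          "external_mapping": {"type": ["string", "null"]}
        }
      }
    },
    "imported_terms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_ontology", "term_uri", "target_superclass"],
        "properties": {
          "label": {"type": "string"},
          "source_ontology": {"type": "string", "format": "uri"},
          "term_uri": {"type": "string", "format": "uri"},
          "target_superclass": {"type": "string", "format": "uri"}
        }
      }
    }
  },
  "definitions": {
    "kind": {
      "enum": [
        "biochemical_entity", "equipment", "temperature", "period", "volume",
        "speed", "concentration", "condition", "goal", "protocol_method",
        "time_point"
      ]
    }
  }
}
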
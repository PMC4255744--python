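{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/protoact/protocol.schema.json",
  "title": "Structured protocol (machine-amenable format)",
  "type": "object",
  "required": ["steps", "unmatched"],
  "properties": {
    "title": {"type": ["string", "null"]},
    "provenance": {
      "type": "object",
      "properties": {
        "author": {"type": ["string", "null"]},
        "source_path": {"type": ["string", "null"]}
      }
    },
    "steps": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["step_index", "action", "descriptors", "missing_essential", "source_sentence"],
        "properties": {
          "step_index": {"type": "integer", "minimum": 1},
          "action": {
            "type": "object",
            "required": ["id", "label"],
            "properties": {
              "id": {"type": "string", "pattern": "^EXACT2_[0-9]{6}$"},
              "label": {"type": "string"}
            }
          },
          "descriptors": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["kind", "relation", "value", "provenance", "essential"],
              "properties": {
                "kind": {"type": "string"},
                "relation": {"enum": ["is-participant-of", "is-proposition", "is-quality-of"]},
                "value": {"type": ["number", "string"]},
                "unit": {"type": ["string", "null"]},
                "unit_id": {"type": ["string", "null"], "pattern": "^UO:[0-9]{7}$"},
                "entity_id": {
                  "type": ["object", "null"],
                  "properties": {
                    "source": {"type": "string"},
                    "value": {"type": "string"}
                  }
                },
                "provenance": {"enum": ["extracted", "default", "inferred", "user"]},
                "essential": {"type": "boolean"}
              }
            }
          },
          "missing_essential": {"type": "array", "items": {"type": "string"}},
          "source_sentence": {"type": "string"},
          "notes": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "unmatched": {"type": "array", "items": {"type": "integer"}}
  }
}
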
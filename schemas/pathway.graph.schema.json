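{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://pathglyph.dev/schemas/pathway.graph.schema.json",
  "title": "Pathway diagram graph (formatVersion 1)",
  "description": "Semantic content of one pathway: every entity including undrawn complex components and set members, plus reaction participation. The children relation must be acyclic; ids are opaque strings, unique within the file, matched to the paired layout by exact string equality.",
  "type": "object",
  "required": ["formatVersion", "pathwayId", "entities", "reactions"],
  "properties": {
    "formatVersion": {"const": 1},
    "pathwayId": {"type": "string", "minLength": 1},
    "entities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "entityType", "displayName"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "entityType": {"enum": ["protein", "chemical", "complex", "entity_set", "other"]},
          "displayName": {"type": "string"},
          "children": {
            "type": "array",
            "items": {"type": "string"},
            "description": "Complex components or set members; empty/absent for leaves."
          }
        },
        "additionalProperties": false
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "inputs": {"type": "array", "items": {"type": "string"}},
          "outputs": {"type": "array", "items": {"type": "string"}},
          "catalysts": {"type": "array", "items": {"type": "string"}},
          "regulators": {"type": "array", "items": {"type": "string"}}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
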
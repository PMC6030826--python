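{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://pathglyph.dev/schemas/pathway.layout.schema.json",
  "title": "Pathway diagram layout (formatVersion 1)",
  "description": "Positioned drawing of one pathway: compartments, entity glyphs and reaction edges. Coordinates are real-valued diagram units, y-down, origin at the canvas top-left; boxes are half-open [x, x+width) x [y, y+height).",
  "type": "object",
  "required": ["formatVersion", "pathwayId", "canvas", "nodes", "edges"],
  "properties": {
    "formatVersion": {"const": 1},
    "pathwayId": {"type": "string", "minLength": 1},
    "canvas": {"$ref": "#/$defs/bbox"},
    "compartments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "displayName", "bbox"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "displayName": {"type": "string"},
          "bbox": {"$ref": "#/$defs/bbox"},
          "containedGlyphIds": {"type": "array", "items": {"type": "string"}}
        },
        "additionalProperties": false
      }
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "renderClass", "displayName", "bbox"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "renderClass": {
            "enum": ["protein", "chemical", "complex", "entity_set", "encapsulated_pathway", "gene", "rna", "other"]
          },
          "displayName": {"type": "string"},
          "bbox": {"$ref": "#/$defs/bbox"},
          "graphRef": {"type": "string", "description": "Graph entity this glyph stands for; defaults to the glyph id. Several glyph instances may share one graphRef."},
          "attachments": {"type": "array", "items": {"type": "string"}},
          "stoichiometry": {"type": "integer", "minimum": 1, "default": 1}
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "segments", "reactionShape"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "segments": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["x1", "y1", "x2", "y2"],
              "properties": {
                "x1": {"type": "number"}, "y1": {"type": "number"},
                "x2": {"type": "number"}, "y2": {"type": "number"}
              },
              "additionalProperties": false
            }
          },
          "reactionShape": {
            "type": "object",
            "required": ["x", "y"],
            "properties": {
              "x": {"type": "number"},
              "y": {"type": "number"},
              "kind": {"type": "string", "default": "transition"}
            },
            "additionalProperties": false
          },
          "connectors": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["role", "glyphId"],
              "properties": {
                "role": {"enum": ["input", "output", "catalyst", "regulator"]},
                "glyphId": {"type": "string"},
                "stoichiometry": {"type": "integer", "minimum": 1, "default": 1}
              },
              "additionalProperties": false
            }
          },
          "graphRef": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false,
  "$defs": {
    "bbox": {
      "type": "object",
      "required": ["x", "y", "width", "height"],
      "properties": {
        "x": {"type": "number"},
        "y": {"type": "number"},
        "width": {"type": "number", "minimum": 0},
        "height": {"type": "number", "minimum": 0}
      },
      "additionalProperties": false
    }
  }
}
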
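{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "prioplan wishlist",
  "description": "Hard constraints and prioritized objectives for automated multicriteria planning. Limits/goals are numbers (Gy), {\"percent_of_prescription\": x} mappings, or dimensionless numbers for LTCP goals.",
  "type": "object",
  "required": ["constraints", "objectives"],
  "properties": {
    "name": {"type": "string"},
    "constraints": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["volume", "metric", "limit"],
        "properties": {
          "volume": {"type": "string"},
          "metric": {"enum": ["max", "mean"]},
          "limit": {"$ref": "#/$defs/doseValue"},
          "fractionation_tolerance_gy": {
            "type": "object",
            "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
          }
        }
      }
    },
    "objectives": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["priority", "volume", "cost", "goal"],
        "properties": {
          "priority": {"type": "integer", "minimum": 1},
          "volume": {"type": "string"},
          "cost": {"enum": ["ltcp", "eud", "mean", "max"]},
          "goal": {"$ref": "#/$defs/doseValue"},
          "alpha": {"type": "number", "exclusiveMinimum": 0},
          "k": {"type": "number", "minimum": 1},
          "cord_conditional": {"type": "boolean"}
        }
      }
    }
  },
  "$defs": {
    "doseValue": {
      "oneOf": [
        {"type": "number", "minimum": 0},
        {
          "type": "object",
          "required": ["percent_of_prescription"],
          "properties": {"percent_of_prescription": {"type": "number", "exclusiveMinimum": 0}},
          "additionalProperties": false
        }
      ]
    }
  }
}
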
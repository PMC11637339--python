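{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hoss-exp-1 experiment definition",
  "type": "object",
  "required": ["format", "id", "protocol", "readouts"],
  "properties": {
    "format": {"const": "hoss-exp-1"},
    "id": {"type": "string", "minLength": 1},
    "protocol": {"enum": ["timeseries", "dose_response", "bar_chart", "direct_parameter"]},
    "weight": {"type": "number", "exclusiveMinimum": 0},
    "settle_time": {"type": "number", "minimum": 0},
    "stimuli": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["entity", "time", "value"],
        "properties": {
          "entity": {"type": "string"},
          "time": {"type": "number"},
          "value": {"type": "number", "minimum": 0},
          "mode": {"enum": ["set_buffered", "set_concentration"]}
        },
        "additionalProperties": false
      }
    },
    "doses": {
      "type": "object",
      "required": ["entity", "values"],
      "properties": {
        "entity": {"type": "string"},
        "values": {"type": "array", "items": {"type": "number"}, "minItems": 1}
      },
      "additionalProperties": false
    },
    "conditions": {
      "type": "array",
      "items": {"type": "object", "additionalProperties": {"type": "number"}},
      "minItems": 1
    },
    "readouts": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["entity", "points"],
        "properties": {
          "entity": {"type": "string"},
          "points": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 3}
          },
          "normalization": {"enum": ["max", "none"]}
        },
        "additionalProperties": false
      }
    },
    "metadata": {"type": "object"}
  },
  "additionalProperties": false
}
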
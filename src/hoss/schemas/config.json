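{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hoss-config-1 pipeline configuration",
  "type": "object",
  "required": ["format", "model", "method"],
  "properties": {
    "format": {"const": "hoss-config-1"},
    "model": {
      "type": "object",
      "required": ["path"],
      "properties": {
        "path": {"type": "string"},
        "format": {"enum": ["sbml", "native"]}
      },
      "additionalProperties": false
    },
    "method": {"enum": ["flat", "hierarchical", "initScram", "hossMC"]},
    "algorithm": {"enum": ["COBYLA", "SLSQP", "BFGS", "NelderMead"]},
    "tolerance": {"type": "number", "exclusiveMinimum": 0},
    "timeout": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "budget": {"type": "integer", "minimum": 0},
    "scramble": {
      "type": "object",
      "properties": {
        "range": {"type": "number", "exclusiveMinimum": 1},
        "count": {"type": "integer", "minimum": 1},
        "distribution": {"enum": ["uniform", "normal"]},
        "rounds": {"type": "integer", "minimum": 1}
      },
      "additionalProperties": false
    },
    "topN": {"type": "integer", "minimum": 1},
    "seed": {"type": "integer", "minimum": 0},
    "output_dir": {"type": "string"},
    "n_jobs": {"type": "integer", "minimum": 1},
    "score_rtol": {"type": "number", "exclusiveMinimum": 0},
    "hierarchy": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["blocks"],
        "properties": {
          "blocks": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["name", "experiments", "params"],
              "properties": {
                "name": {"type": "string"},
                "experiments": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["path"],
                    "properties": {
                      "path": {"type": "string"},
                      "weight": {"type": "number", "exclusiveMinimum": 0}
                    },
                    "additionalProperties": false
                  }
                },
                "params": {"type": "array", "items": {"type": "string"}},
                "bounds": {
                  "type": "object",
                  "additionalProperties": {
                    "type": "array",
                    "items": {"type": "number"},
                    "minItems": 2,
                    "maxItems": 2
                  }
                }
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    },
    "auto_hierarchy": {
      "type": "object",
      "properties": {
        "r": {"type": ["integer", "null"], "minimum": 1},
        "use_agony": {"type": "boolean"},
        "qss_reduce": {"type": "boolean"},
        "irreversibility": {"type": "array", "items": {"type": "string"}},
        "experiments": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["path"],
            "properties": {
              "path": {"type": "string"},
              "weight": {"type": "number", "exclusiveMinimum": 0}
            },
            "additionalProperties": false
          }
        }
      },
      "additionalProperties": false
    }
  },
  "oneOf": [
    {"required": ["hierarchy"], "not": {"required": ["auto_hierarchy"]}},
    {"required": ["auto_hierarchy"], "not": {"required": ["hierarchy"]}}
  ],
  "additionalProperties": false
}
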
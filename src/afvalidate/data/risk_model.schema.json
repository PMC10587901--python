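{
  "$defs": {
    "Term": {
      "additionalProperties": false,
      "properties": {
        "covariate": {
          "title": "Covariate",
          "type": "string"
        },
        "transform": {
          "$ref": "#/$defs/Transform"
        },
        "beta": {
          "title": "Beta",
          "type": "number"
        }
      },
      "required": [
        "covariate",
        "beta"
      ],
      "title": "Term",
      "type": "object"
    },
    "Transform": {
      "additionalProperties": false,
      "description": "Descriptor of the covariate transform applied inside one term.",
      "properties": {
        "type": {
          "enum": [
            "linear",
            "log",
            "indicator",
            "equals",
            "hinge"
          ],
          "title": "Type",
          "type": "string"
        },
        "knot": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Knot"
        },
        "level": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Level"
        }
      },
      "required": [
        "type"
      ],
      "title": "Transform",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "A validated coefficient file: terms, centering and baseline survival.",
  "properties": {
    "model_id": {
      "title": "Model Id",
      "type": "string"
    },
    "outcome": {
      "enum": [
        "death",
        "stroke_se",
        "major_bleed"
      ],
      "title": "Outcome",
      "type": "string"
    },
    "description": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Description"
    },
    "terms": {
      "items": {
        "$ref": "#/$defs/Term"
      },
      "title": "Terms",
      "type": "array"
    },
    "centering": {
      "anyOf": [
        {
          "const": "precentered",
          "type": "string"
        },
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        }
      ],
      "title": "Centering"
    },
    "baseline_survival": {
      "additionalProperties": {
        "type": "number"
      },
      "description": "map from horizon in months to S0(t) in (0, 1]",
      "title": "Baseline Survival",
      "type": "object"
    }
  },
  "required": [
    "model_id",
    "outcome",
    "terms",
    "centering",
    "baseline_survival"
  ],
  "title": "RiskModelSpec",
  "type": "object"
}
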
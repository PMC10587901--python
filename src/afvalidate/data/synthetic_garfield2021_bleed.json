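{
  "model_id": "garfield2021_bleed",
  "outcome": "major_bleed",
  "description": "SYNTHETIC stand-in for the 2021 major bleeding equation. Invented coefficients.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.044,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.9,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "prior_stroke_tia",
      "beta": 0.2,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "vascular_disease",
      "beta": 0.14,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "antiplatelet_or_nsaid",
      "beta": 0.3,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "current_smoker",
      "beta": 0.18,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ckd_grade3plus",
      "beta": 0.2,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "oac",
      "beta": 0.26,
      "transform": {
        "type": "indicator"
      }
    }
  ],
  "centering": {
    "age": 74.6,
    "bleeding_history": 0.0,
    "prior_stroke_tia": 0.0,
    "vascular_disease": 0.0,
    "antiplatelet_or_nsaid": 0.0,
    "current_smoker": 0.0,
    "ckd_grade3plus": 0.0,
    "oac": 0.0
  },
  "baseline_survival": {
    "1": 0.998826,
    "12": 0.986,
    "24": 0.972196
  }
}
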
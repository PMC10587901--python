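{
  "model_id": "garfield2017_bleed",
  "outcome": "major_bleed",
  "description": "SYNTHETIC stand-in for the 2017 major bleeding equation. Invented coefficients.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.042,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.88,
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
      "beta": 0.15,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "antiplatelet_or_nsaid",
      "beta": 0.28,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "oac",
      "beta": 0.25,
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
    "oac": 0.0
  },
  "baseline_survival": {
    "12": 0.987
  }
}
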
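{
  "model_id": "garfield2017_death_reduced",
  "outcome": "death",
  "description": "SYNTHETIC stand-in for the reduced 2017 all-cause death equation: same covariate structure as the published abridged model, invented coefficients. Not the licensed published values.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.072,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "pulse",
      "beta": 0.011,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "sbp",
      "beta": -0.007,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "vascular_disease",
      "beta": 0.32,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.22,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "chf",
      "beta": 0.58,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ckd_grade3plus",
      "beta": 0.42,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "oac",
      "beta": -0.3,
      "transform": {
        "type": "indicator"
      }
    }
  ],
  "centering": {
    "age": 74.6,
    "pulse": 79.2,
    "sbp": 134.8,
    "vascular_disease": 0.0,
    "bleeding_history": 0.0,
    "chf": 0.0,
    "ckd_grade3plus": 0.0,
    "oac": 0.0
  },
  "baseline_survival": {
    "12": 0.92
  }
}
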
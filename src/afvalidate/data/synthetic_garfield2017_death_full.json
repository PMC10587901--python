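{
  "model_id": "garfield2017_death_full",
  "outcome": "death",
  "description": "SYNTHETIC stand-in for the full 2017 death equation (wider covariate set incl. vitals, diabetes, smoking, dementia). Invented coefficients.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.07,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "pulse",
      "beta": 0.01,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "sbp",
      "beta": -0.006,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "weight",
      "beta": -0.004,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "diabetes",
      "beta": 0.28,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "current_smoker",
      "beta": 0.46,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "dementia",
      "beta": 0.85,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "vascular_disease",
      "beta": 0.3,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.2,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "chf",
      "beta": 0.55,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ckd_grade3plus",
      "beta": 0.4,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "cirrhosis",
      "beta": 0.9,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "oac",
      "beta": -0.28,
      "transform": {
        "type": "indicator"
      }
    }
  ],
  "centering": {
    "age": 74.6,
    "pulse": 79.2,
    "sbp": 134.8,
    "weight": 81.3,
    "diabetes": 0.0,
    "current_smoker": 0.0,
    "dementia": 0.0,
    "vascular_disease": 0.0,
    "bleeding_history": 0.0,
    "chf": 0.0,
    "ckd_grade3plus": 0.0,
    "cirrhosis": 0.0,
    "oac": 0.0
  },
  "baseline_survival": {
    "12": 0.915
  }
}
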
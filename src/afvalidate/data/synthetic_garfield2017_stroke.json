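{
  "model_id": "garfield2017_stroke",
  "outcome": "stroke_se",
  "description": "SYNTHETIC stand-in for the 2017 ischaemic stroke / systemic embolism equation (age, prior stroke, bleeding, heart failure, CKD, ethnicity, anticoagulation). Invented coefficients.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.05,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "prior_stroke_tia",
      "beta": 0.78,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.15,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "chf",
      "beta": 0.22,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ckd_grade3plus",
      "beta": 0.18,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ethnicity",
      "beta": 0.12,
      "transform": {
        "type": "equals",
        "level": "asian"
      }
    },
    {
      "covariate": "oac",
      "beta": -0.35,
      "transform": {
        "type": "indicator"
      }
    }
  ],
  "centering": {
    "age": 74.6,
    "prior_stroke_tia": 0.0,
    "bleeding_history": 0.0,
    "chf": 0.0,
    "ckd_grade3plus": 0.0,
    "oac": 0.0,
    "ethnicity": 0.0
  },
  "baseline_survival": {
    "12": 0.984
  }
}
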
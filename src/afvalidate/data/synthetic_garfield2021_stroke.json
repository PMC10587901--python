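{
  "model_id": "garfield2021_stroke",
  "outcome": "stroke_se",
  "description": "SYNTHETIC stand-in for the 2021 stroke/SE equation (2017 covariates plus female sex, carotid occlusive disease, dementia, smoking). Invented coefficients.",
  "terms": [
    {
      "covariate": "age",
      "beta": 0.052,
      "transform": {
        "type": "linear"
      }
    },
    {
      "covariate": "prior_stroke_tia",
      "beta": 0.8,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "bleeding_history",
      "beta": 0.14,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "chf",
      "beta": 0.2,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "ckd_grade3plus",
      "beta": 0.16,
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
      "covariate": "sex",
      "beta": 0.12,
      "transform": {
        "type": "equals",
        "level": "female"
      }
    },
    {
      "covariate": "carotid_occlusive_disease",
      "beta": 0.35,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "dementia",
      "beta": 0.25,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "current_smoker",
      "beta": 0.2,
      "transform": {
        "type": "indicator"
      }
    },
    {
      "covariate": "oac",
      "beta": -0.36,
      "transform": {
        "type": "indicator"
      }
    }
  ],
  "centering": {
    "age": 74.6,
    "sex": 0.0,
    "ethnicity": 0.0,
    "prior_stroke_tia": 0.0,
    "bleeding_history": 0.0,
    "chf": 0.0,
    "ckd_grade3plus": 0.0,
    "carotid_occlusive_disease": 0.0,
    "dementia": 0.0,
    "current_smoker": 0.0,
    "oac": 0.0
  },
  "baseline_survival": {
    "1": 0.998741,
    "12": 0.985,
    "24": 0.970225
  }
}
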
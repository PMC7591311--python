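{
  "stunting_ne": {
    "outcome": "stunted",
    "region": "north_eastern",
    "lnodds_mean": -1.109,
    "outcome_ci": 0.196,
    "group_percents": {
      "age": -2.03, "gender": -0.82, "education": 18.56, "wealth": 61.45,
      "cfi": -0.15, "birth_certificate": -0.31, "campaign": 6.86,
      "sanitation": 2.71, "water_treatment": -0.95, "water_source": 14.67
    },
    "group_flags": []
  },
  "stunting_pp": {
    "outcome": "stunted",
    "region": "phnom_penh",
    "lnodds_mean": -1.874,
    "outcome_ci": 0.068,
    "group_percents": {
      "age": -3.47, "gender": 4.31, "education": 19.47, "wealth": 67.54,
      "cfi": -2.00, "birth_certificate": 9.37, "campaign": -0.76,
      "sanitation": 1.44, "water_treatment": 4.10, "water_source": null
    },
    "group_flags": ["gender", "education"]
  },
  "wasting_ne": {
    "outcome": "wasted",
    "region": "north_eastern",
    "lnodds_mean": -1.7832,
    "outcome_ci": 0.0782,
    "group_percents": {
      "age": -0.25, "gender": 1.33, "education": 14.24, "wealth": 51.16,
      "cfi": -3.32, "birth_certificate": 1.17, "campaign": 7.2,
      "sanitation": 25.96, "water_treatment": -18.06, "water_source": 20.56
    },
    "group_flags": []
  }
}
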
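{
  "_comment": "Calibrated default generator configuration. Effect sizes are odds ratios; covariates whose effects are only reported qualitatively carry modest defaults in the reported direction; unreported effects are 1. Intercepts (log-odds) are calibrated so pooled indicator prevalences are ~21/31/36%.",
  "design": {
    "n_districts": 24,
    "n_clusters": 1064,
    "households_per_cluster": 30,
    "rounds": 8
  },
  "zones": {"labels": ["NW", "NE", "SC"], "weights": [0.22, 0.15, 0.63]},
  "livelihoods": {
    "labels": ["agro-pastoral", "pastoral", "riverine", "IDP", "urban"],
    "weights": [0.42, 0.27, 0.16, 0.11, 0.04]
  },
  "covariate_marginals": {
    "female": 0.5,
    "fever": 0.21,
    "diarrhoea": 0.17,
    "ari": 0.26,
    "measles": 0.5,
    "polio": 0.82,
    "vita": 0.5,
    "access_protein": 0.92,
    "access_carb": 0.92,
    "access_fruitveg": 0.41
  },
  "household": {
    "size_mean": 6.0,
    "under5_mean": 2.0,
    "under5_min": 1,
    "under5_max": 4,
    "head_female": 0.19,
    "mother_age_mean": 31.0,
    "mother_age_sd": 7.0,
    "mother_muac_mean": 255.0,
    "mother_muac_sd": 25.0
  },
  "effects_or": {
    "wasting": {
      "female": 0.73,
      "age_12_23": 0.85,
      "age_24_59": 0.75,
      "fever": 1.25,
      "diarrhoea": 1.35,
      "ari": 1.15,
      "polio": 0.88,
      "vita": 0.9,
      "access_protein": 0.85,
      "access_carb": 0.88,
      "household_size": 1.03,
      "n_under5": 1.05,
      "mother_muac_mm": 0.997,
      "evi": 0.62
    },
    "stunting": {
      "female": 0.73,
      "age_12_23": 2.2,
      "age_24_59": 2.3,
      "fever": 1.2,
      "diarrhoea": 1.29,
      "ari": 1.1,
      "access_protein": 0.9,
      "access_carb": 0.9,
      "access_fruitveg": 1.1,
      "household_size": 1.03,
      "n_under5": 1.05,
      "mother_muac_mm": 0.997,
      "evi": 0.51
    },
    "low_muac": {
      "female": 1.24,
      "age_12_23": 0.8,
      "age_24_59": 0.6,
      "fever": 1.2,
      "diarrhoea": 1.2,
      "ari": 1.1,
      "vita": 0.9,
      "access_protein": 0.9,
      "household_size": 1.02,
      "n_under5": 1.04,
      "mother_muac_mm": 0.996,
      "evi": 0.41
    }
  },
  "intercept": {"wasting": 0.061, "stunting": -0.579, "low_muac": 1.035},
  "season_or_gu": {"wasting": 0.88, "stunting": 1.0, "low_muac": 0.9},
  "precisions": {"spatial": 25.0, "unstruct": 25.0, "district": 25.0, "temporal": 100.0},
  "env_fields": {
    "evi": {"range_km": 110.0, "variance": 1.0, "bounds": [0.0, 1.0]},
    "rainfall": {"range_km": 160.0, "variance": 1.0, "bounds": [0.0, 600.0]},
    "temperature": {"range_km": 220.0, "variance": 1.0, "bounds": [18.0, 38.0]}
  },
  "muac_sd": 11.0
}
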
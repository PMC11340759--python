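{
  "config_hash": "fcb425910b0a368ea4b5aa405e3d3e5fc384d1f301fa7200142828ff6ceff7fd",
  "stages": {
    "engraft": {
      "n_engrafted": 429,
      "rows": 1450
    },
    "integrate": {
      "first_canonical_correlation": 0.999999883089,
      "lambda1": 0.0001,
      "lambda2": 0.00039810717055349735,
      "n_complete_cases": 19,
      "rows": 6
    },
    "linkstats": {
      "procrustes_m2": 0.979835514257,
      "procrustes_p": 0.841,
      "rows": 6
    },
    "metrics": {
      "beta_donor_post": [
        -0.382601870178,
        -0.40051196239,
        -0.367044890371
      ],
      "rows": 58
    },
    "simulate": {
      "n_sgb": 50,
      "rows": 29
    },
    "thresholds": {
      "n_estimable": 50,
      "rows": 50
    }
  }
}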
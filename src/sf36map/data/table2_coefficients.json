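{
  "source_doi": "10.1186/s12955-014-0145-9",
  "source_table": "Table 2 (derivation set)",
  "note": "OLS mapping coefficients from the Korean SF-36 to EQ-5D crosswalk study. The source does not state the covariate units used at fit time; see the scale-convention caveat in sf36map.published. 'significant' is false for terms the source marks p > 0.05.",
  "models": {
    "m1": {
      "terms": [
        {"term": "Intercept", "beta": 0.0161, "se": 0.1019, "significant": false},
        {"term": "PF", "beta": 0.0179, "se": 0.0030, "significant": true},
        {"term": "RP", "beta": 0.0010, "se": 0.0014, "significant": false},
        {"term": "BP", "beta": 0.0051, "se": 0.0013, "significant": true},
        {"term": "GH", "beta": 0.0003, "se": 0.0004, "significant": false},
        {"term": "VT", "beta": -0.0018, "se": 0.0021, "significant": false},
        {"term": "SF", "beta": 0.0162, "se": 0.0024, "significant": true},
        {"term": "RE", "beta": 0.0102, "se": 0.0040, "significant": true},
        {"term": "MH", "beta": 0.0050, "se": 0.0005, "significant": true}
      ],
      "reported": {"r2": 0.6807, "mae": 0.101, "rmse": 0.150, "ae_gt_05": 53.1, "ae_gt_10": 33.9, "pred_mean": 0.816, "pred_sd": 0.220, "pred_min": 0.291, "pred_max": 1.057}
    },
    "m2": {
      "terms": [
        {"term": "Intercept", "beta": 0.0168, "se": 0.0999, "significant": false},
        {"term": "PF", "beta": 0.0180, "se": 0.0027, "significant": true},
        {"term": "BP", "beta": 0.0050, "se": 0.0009, "significant": true},
        {"term": "SF", "beta": 0.0166, "se": 0.0022, "significant": true},
        {"term": "RE", "beta": 0.0107, "se": 0.0036, "significant": true},
        {"term": "MH", "beta": 0.0043, "se": 0.0013, "significant": true}
      ],
      "reported": {"r2": 0.6804, "mae": 0.101, "rmse": 0.150, "ae_gt_05": 52.7, "ae_gt_10": 34.3, "pred_mean": 0.816, "pred_sd": 0.220, "pred_min": 0.293, "pred_max": 1.049}
    },
    "m3": {
      "terms": [
        {"term": "Intercept", "beta": -0.7629, "se": 0.1066, "significant": true},
        {"term": "PF", "beta": 0.0696, "se": 0.0091, "significant": true},
        {"term": "BP", "beta": 0.0114, "se": 0.0007, "significant": true},
        {"term": "GH", "beta": 0.0029, "se": 0.0011, "significant": true},
        {"term": "SF", "beta": 0.0656, "se": 0.0086, "significant": true},
        {"term": "RE", "beta": 0.0432, "se": 0.0054, "significant": true},
        {"term": "MH", "beta": 0.0058, "se": 0.0011, "significant": true},
        {"term": "PF squared", "beta": -0.0013, "se": 0.0002, "significant": true},
        {"term": "SF squared", "beta": -0.0042, "se": 0.0005, "significant": true},
        {"term": "RE squared", "beta": -0.0018, "se": 0.0002, "significant": true}
      ],
      "reported": {"r2": 0.7476, "mae": 0.087, "rmse": 0.134, "ae_gt_05": 49.6, "ae_gt_10": 28.0, "pred_mean": 0.816, "pred_sd": 0.230, "pred_min": 0.099, "pred_max": 1.020}
    },
    "m4": {
      "terms": [
        {"term": "Intercept", "beta": -0.6947, "se": 0.0861, "significant": true},
        {"term": "PF", "beta": 0.0720, "se": 0.0092, "significant": true},
        {"term": "BP", "beta": 0.0115, "se": 0.0007, "significant": true},
        {"term": "GH", "beta": 0.0024, "se": 0.0010, "significant": true},
        {"term": "SF", "beta": 0.0644, "se": 0.0082, "significant": true},
        {"term": "RE", "beta": 0.0418, "se": 0.0055, "significant": true},
        {"term": "MH", "beta": 0.0058, "se": 0.0011, "significant": true},
        {"term": "PF squared", "beta": -0.0014, "se": 0.0002, "significant": true},
        {"term": "SF squared", "beta": -0.0041, "se": 0.0005, "significant": true},
        {"term": "RE squared", "beta": -0.0017, "se": 0.0002, "significant": true},
        {"term": "Age", "beta": -0.0011, "se": 0.0003, "significant": true}
      ],
      "reported": {"r2": 0.7498, "mae": 0.087, "rmse": 0.133, "ae_gt_05": 50.0, "ae_gt_10": 28.4, "pred_mean": 0.816, "pred_sd": 0.230, "pred_min": 0.091, "pred_max": 1.037}
    },
    "m5": {
      "terms": [
        {"term": "Intercept", "beta": 0.9277, "se": 0.0040, "significant": true},
        {"term": "PCS", "beta": 0.1227, "se": 0.0182, "significant": true},
        {"term": "MCS", "beta": 0.0769, "se": 0.0128, "significant": true}
      ],
      "reported": {"r2": 0.6366, "mae": 0.109, "rmse": 0.160, "ae_gt_05": 62.8, "ae_gt_10": 36.8, "pred_mean": 0.816, "pred_sd": 0.212, "pred_min": 0.285, "pred_max": 1.111}
    },
    "m6": {
      "terms": [
        {"term": "Intercept", "beta": 0.9582, "se": 0.0059, "significant": true},
        {"term": "PCS", "beta": 0.0509, "se": 0.0046, "significant": true},
        {"term": "MCS", "beta": 0.0196, "se": 0.0029, "significant": true},
        {"term": "PCS x PCS", "beta": -0.0265, "se": 0.0037, "significant": true},
        {"term": "MCS x MCS", "beta": -0.0113, "se": 0.0015, "significant": true},
        {"term": "PCS x MCS", "beta": -0.0334, "se": 0.0034, "significant": true}
      ],
      "reported": {"r2": 0.7093, "mae": 0.094, "rmse": 0.143, "ae_gt_05": 50.4, "ae_gt_10": 29.3, "pred_mean": 0.816, "pred_sd": 0.224, "pred_min": -0.002, "pred_max": 0.997}
    }
  }
}
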
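{
  "annotation": {
    "ms2_cutoff": 85.0,
    "mz_tol_ppm": 5.0,
    "rt_tol_min": 0.2
  },
  "imputation": {
    "max_iter": 10,
    "n_trees": 100
  },
  "network": {
    "frag_tol": 0.0025,
    "min_coverage": 70.0,
    "min_fragments": 3,
    "min_score": 50.0
  },
  "normalization": {
    "reference": "max"
  },
  "opls_da": {
    "dq2_min": 0.01,
    "max_orthogonal": 3,
    "n_folds": 7
  },
  "peak_rating": {
    "min_rating": 5.0,
    "min_samples": 5
  },
  "qc_correction": {
    "n_predictors": 10,
    "n_trees": 200
  },
  "rsd_filter": {
    "max_after": 25.0,
    "max_before": 50.0
  },
  "screening": {
    "max_depth": 2,
    "tol_ppm": 5.0
  },
  "selection": {
    "cv_anova_alpha": 0.05,
    "p_max": 0.05,
    "pcorr_min": 0.5,
    "vip_min": 1.5
  },
  "usable_hits": {
    "min_fraction": 0.8
  }
}
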
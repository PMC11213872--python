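"""Published default parameters for every pipeline stage, as data.

These are the documented settings of the original acquisition/processing
workflow the pipeline re-implements; the CLI echoes them into every run
report so a processed dataset is self-describing.
"""

DEFAULTS: dict = {
    "peak_rating": {"min_rating": 5.0, "min_samples": 5},
    "imputation": {"n_trees": 100, "max_iter": 10},
    "qc_correction": {"n_trees": 200, "n_predictors": 10},
    "rsd_filter": {"max_before": 50.0, "max_after": 25.0},
    "usable_hits": {"min_fraction": 0.80},
    "normalization": {"reference": "max"},
    "opls_da": {"n_folds": 7, "max_orthogonal": 3, "dq2_min": 0.01},
    "selection": {"vip_min": 1.5, "pcorr_min": 0.50, "p_max": 0.05,
                  "cv_anova_alpha": 0.05},
    "screening": {"tol_ppm": 5.0, "max_depth": 2},
    "network": {"min_score": 50.0, "min_fragments": 3, "min_coverage": 70.0,
                "frag_tol": 0.0025},
    "annotation": {"mz_tol_ppm": 5.0, "rt_tol_min": 0.2, "ms2_cutoff": 85.0},
}
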
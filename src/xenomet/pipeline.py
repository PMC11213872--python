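"""Feature-table quality control, drift correction, filtering and scaling.

The stage order mirrors standard untargeted LC-HRMS practice:

1. ``filter_by_peak_rating`` — drop low-quality peaks (vendor rating > 5 in at
   least 5 samples).
2. ``impute_missing`` — random-forest (missForest-style) imputation, 100 trees,
   max 10 iterations.
3. ``qc_correct`` — SERRF-style per-feature random-forest drift model fitted on
   pooled-QC injections (200 trees, single batch), interpolated at study
   injection orders by monotone piecewise-cubic regression.
4. ``rsd_filter`` — QC RSD <= 50% before correction and <= 25% after.
5. ``usable_hits_filter`` — feature detected in >= 80% of the samples of at
   least one group x timepoint cell (pre-imputation detection mask).
6. ``normalize_median`` — scale each sample to the maximum per-sample median.
7. ``log_pareto`` — natural log, mean-center, divide by sqrt(sd).

Boundary conventions: "rating above 5" is strict (>); "maximum RSD allowed"
is non-strict (<=).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import PchipInterpolator
from sklearn.ensemble import RandomForestRegressor

from .featuretable import FeatureTable, QcReport, qc_rsd

log = logging.getLogger(__name__)


def filter_by_peak_rating(
    table: FeatureTable,
    min_rating: float = 5.0,
    min_samples: int = 5,
    report: QcReport | None = None,
) -> FeatureTable:
    """Keep features rated strictly above ``min_rating`` in >= ``min_samples``
    samples."""
    if table.ratings is None:
        raise ValueError(
            "peak ratings missing: supply a samples x features rating frame as "
            "FeatureTable.ratings (vendor 'Original Peak Rating' or equivalent)"
        )
    good = (table.ratings > min_rating).sum(axis=0) >= min_samples
    out = table.select_features(table.values.columns[good])
    if report is not None:
        report.record(
            "filter_by_peak_rating", out, min_rating=min_rating, min_samples=min_samples
        )
    return out


def impute_missing(
    table: FeatureTable,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    report: QcReport | None = None,
) -> FeatureTable:
    """Random-forest missing-value imputation (missForest scheme).

    Iterative per-feature regression with a random forest; observed entries
    are never changed, and the result is reproducible for a given seed.
    Features missing in more than half the samples are flagged (warning);
    all-missing features are rejected.
    """
    values = table.values
    missing = values.isna()
    if not missing.any().any():
        out = table.copy()
        if report is not None:
            report.record("impute_missing", out, n_trees=n_trees, max_iter=max_iter,
                          seed=seed, n_missing=0)
        return out
    all_missing = missing.all(axis=0)
    if all_missing.any():
        raise ValueError(
            "cannot impute all-missing features: "
            f"{list(values.columns[all_missing])}"
        )
    frac = missing.mean(axis=0)
    heavy = list(values.columns[frac > 0.5])
    if heavy:
        log.warning("%d features are >50%% missing: %s ...", len(heavy), heavy[:5])
    # Impute on a log scale: intensities are log-normal and the censoring is
    # intensity-dependent, so trees trained on logs extrapolate less wildly.
    logged = np.log(values.where(values > 0)).to_numpy(float)
    filled_log = _miss_forest(logged, n_trees, max_iter, seed)
    filled = pd.DataFrame(
        np.exp(filled_log), index=values.index, columns=values.columns
    )
    filled = values.where(~missing, filled)  # observed entries unchanged
    out = table.copy()
    out.values = filled
    if report is not None:
        report.record(
            "impute_missing", out, n_trees=n_trees, max_iter=max_iter, seed=seed,
            n_missing=int(missing.to_numpy().sum()),
        )
    return out


def _miss_forest(
    X: np.ndarray,
    n_trees: int,
    max_iter: int,
    seed: int,
    n_predictors: int = 10,
) -> np.ndarray:
    """missForest-style iterative random-forest imputation.

    Starts from per-feature medians; per sweep, each feature with missing
    entries is regressed on the ``n_predictors`` most correlated other
    features (random forest, ``n_trees`` trees, mtry = sqrt) and its missing
    entries re-predicted.  Sweeps stop at ``max_iter`` or as soon as the
    relative change in imputed values increases (the missForest stopping
    statistic); the imputation from before the increase is returned.
    """
    X = X.copy()
    missing = np.isnan(X)
    med = np.nanmedian(X, axis=0)
    X[missing] = np.take(med, np.where(missing)[1])

    cols = np.where(missing.any(axis=0))[0]
    # sweep order: least missing first, as in missForest
    cols = cols[np.argsort(missing[:, cols].sum(axis=0), kind="stable")]
    rng = np.random.default_rng(seed)
    col_seeds = {int(j): int(s)
                 for j, s in zip(cols, rng.integers(0, 2**31 - 1, len(cols)))}

    prev = X.copy()
    best = X.copy()
    prev_delta = np.inf
    for _ in range(max_iter):
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, np.nan)
        for j in cols:
            c = np.abs(corr[:, j])
            c[np.isnan(c)] = -1.0
            k = min(n_predictors, X.shape[1] - 1)
            pred_cols = np.argsort(c, kind="stable")[-k:]
            obs = ~missing[:, j]
            rf = RandomForestRegressor(
                n_estimators=n_trees, random_state=col_seeds[int(j)],
                max_features="sqrt", n_jobs=1,
            )
            rf.fit(X[np.ix_(obs, pred_cols)], X[obs, j])
            X[missing[:, j], j] = rf.predict(X[np.ix_(missing[:, j], pred_cols)])
        diff = (X - prev)[missing]
        delta = float((diff**2).sum() / max((X[missing] ** 2).sum(), 1e-300))
        if delta >= prev_delta:
            return best  # change increased: keep previous sweep's imputation
        best = X.copy()
        prev = X.copy()
        prev_delta = delta
    return best


def _drift_curve(
    y_qc: np.ndarray,
    x_qc: np.ndarray,
    predictors_qc: np.ndarray,
    x_all: np.ndarray,
    n_trees: int,
    seed: int,
) -> np.ndarray | None:
    """Fit the per-feature drift model on QC injections and return the
    multiplicative drift factor at every injection order, or None when the
    model does not beat predicting the mean (out-of-bag R^2 <= 0)."""
    X_qc = np.column_stack([x_qc[:, None], predictors_qc])
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        random_state=seed,
        oob_score=True,
        bootstrap=True,
        n_jobs=1,
    )
    rf.fit(X_qc, y_qc)
    if not np.isfinite(rf.oob_score_) or rf.oob_score_ <= 0.0:
        return None
    # Drift evaluated at QC orders, then interpolated at every injection
    # order with a monotone piecewise cubic ("non-linear regression").
    pred_qc = rf.predict(X_qc)
    order = np.argsort(x_qc)
    interp = PchipInterpolator(x_qc[order], pred_qc[order], extrapolate=True)
    drift = interp(x_all)
    # Guard: drift factors must stay positive.
    floor = 0.05 * np.median(np.abs(pred_qc))
    return np.maximum(drift, floor if floor > 0 else 1e-12)


def qc_correct(
    table: FeatureTable,
    n_trees: int = 200,
    n_predictors: int = 10,
    gate_alpha: float = 0.01,
    seed: int = 0,
    report: QcReport | None = None,
) -> tuple[FeatureTable, QcReport]:
    """SERRF-style QC-based signal-drift correction, samples as one batch.

    Per feature, a random forest (``n_trees``) regresses the QC intensities on
    injection order plus the ``n_predictors`` most QC-correlated other
    features.  The fitted drift is interpolated at every injection order and
    intensities are divided by it, rescaled so each feature's QC median is
    preserved exactly.

    A feature is corrected only when (a) its QC intensities show a
    significant rank association with injection order (Spearman test at
    ``gate_alpha``) and (b) the forest beats the mean out-of-bag; otherwise
    it passes through unchanged, because dividing by a noise fit inflates
    rather than removes variance.  The gate makes the correction monotone-
    drift-seeking; drift with zero net trend across the run is left alone.
    """
    if report is None:
        report = QcReport()
    qc_mask = table.mask("qc").to_numpy()
    if qc_mask.sum() < 5:
        raise ValueError(
            f"need >= 5 QC samples spread across the run, got {int(qc_mask.sum())}"
        )
    if table.values.isna().any().any():
        raise ValueError("qc_correct requires an imputed (complete) table")
    report.rsd_before = qc_rsd(table)

    V = table.values.to_numpy(float)
    x_all = table.sample_meta["injection_order"].to_numpy(float)
    x_qc = x_all[qc_mask]
    Q = V[qc_mask]  # QC intensities, n_qc x p
    n_qc, p = Q.shape

    # QC correlation matrix for predictor selection (constant features -> 0).
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = Q.std(axis=0)
        Z = (Q - Q.mean(axis=0)) / np.where(sd > 0, sd, np.inf)
    corr = np.abs(Z.T @ Z) / n_qc
    np.fill_diagonal(corr, -np.inf)

    corrected = V.copy()
    n_corrected = 0
    rng = np.random.default_rng(seed)
    feature_seeds = rng.integers(0, 2**31 - 1, size=p)
    for j in range(p):
        y_qc = Q[:, j]
        if np.ptp(y_qc) == 0:  # exact: std of a constant array can round
            log.debug("feature %s constant in QCs; passed through", j)
            continue
        # Drift-evidence gate: correct only features whose QC intensities
        # show an injection-order association (rank test).  The forest's
        # correlated-feature predictors are selected from the same QC data,
        # so its out-of-bag score alone cannot tell drift from selection
        # bias; this gate can, because it never selects.
        rho_p = sps.spearmanr(x_qc, y_qc).pvalue
        if not np.isfinite(rho_p) or rho_p > gate_alpha:
            continue
        k = min(n_predictors, p - 1)
        top = np.argpartition(corr[:, j], -k)[-k:] if k > 0 else np.array([], int)
        drift = _drift_curve(
            y_qc, x_qc, Q[:, top], x_all,
            n_trees=n_trees, seed=int(feature_seeds[j]),
        )
        if drift is None:
            continue
        ratio = V[:, j] / drift
        qc_ratio = ratio[qc_mask]
        med_raw = np.median(y_qc)
        med_ratio = np.median(qc_ratio)
        if med_ratio <= 0:
            continue
        corrected[:, j] = ratio * (med_raw / med_ratio)
        n_corrected += 1

    out = table.copy()
    out.values = pd.DataFrame(
        corrected, index=table.values.index, columns=table.values.columns
    )
    report.rsd_after = qc_rsd(out)
    report.record(
        "qc_correct", out, n_trees=n_trees, n_predictors=n_predictors, seed=seed,
        n_corrected=n_corrected,
    )
    return out, report


def rsd_filter(
    table: FeatureTable,
    report: QcReport,
    max_before: float = 50.0,
    max_after: float = 25.0,
) -> FeatureTable:
    """Drop features whose QC RSD exceeded ``max_before``% before correction or
    ``max_after``% after (both bounds inclusive: 'maximum allowed')."""
    if report.rsd_before is None or report.rsd_after is None:
        raise ValueError("rsd_filter needs a QcReport produced by qc_correct")
    before = report.rsd_before.reindex(table.values.columns)
    after = report.rsd_after.reindex(table.values.columns)
    ok = (before <= max_before) & (after <= max_after)
    ok &= before.notna() & after.notna()
    out = table.select_features(table.values.columns[ok])
    report.record("rsd_filter", out, max_before=max_before, max_after=max_after)
    return out


def usable_hits_filter(
    table: FeatureTable,
    min_fraction: float = 0.80,
    report: QcReport | None = None,
) -> FeatureTable:
    """Keep features detected (pre-imputation) in >= ``min_fraction`` of the
    samples of at least one group x timepoint cell of study samples."""
    if table.detected is None:
        raise ValueError(
            "usable_hits_filter needs the pre-imputation detection mask "
            "(FeatureTable.detected)"
        )
    meta = table.sample_meta
    study = meta["role"] == "study"
    keep = pd.Series(False, index=table.values.columns)
    for (_, _), idx in meta[study].groupby(["group", "timepoint"], observed=True).groups.items():
        det = table.detected.loc[idx]
        keep |= det.mean(axis=0) >= min_fraction
    out = table.select_features(table.values.columns[keep])
    if report is not None:
        report.record("usable_hits_filter", out, min_fraction=min_fraction)
    return out


def normalize_median(
    table: FeatureTable,
    reference: str = "max",
    report: QcReport | None = None,
) -> FeatureTable:
    """Scale every sample so its median feature area equals the reference
    median (maximum of the per-sample medians by default; ``reference="median"``
    selects median-of-medians).  Blank/solvent/medium-control samples are
    excluded from the reference but still scaled."""
    if table.values.isna().any().any():
        raise ValueError("normalize_median requires a complete table")
    medians = table.values.median(axis=1)
    zero = medians[medians <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with non-positive median area: {list(zero.index)}")
    informative = table.sample_meta["role"].isin(["qc", "study"])
    ref_pool = medians[informative] if informative.any() else medians
    ref = ref_pool.max() if reference == "max" else ref_pool.median()
    factors = ref / medians
    out = table.copy()
    out.values = table.values.mul(factors, axis=0)
    if report is not None:
        report.record("normalize_median", out, reference=reference,
                      reference_median=float(ref))
    return out


def log_pareto(
    table: FeatureTable,
    report: QcReport | None = None,
) -> FeatureTable:
    """Natural log transform, then Pareto scale (center, divide by sqrt(sd)).

    Features that are constant after the log (sd = 0) cannot be scaled and are
    dropped with a warning.  After scaling, each feature's variance equals its
    pre-scaling standard deviation.
    """
    vals = table.values
    n_bad = int((vals <= 0).to_numpy().sum())
    if n_bad:
        raise ValueError(f"log transform requires positive areas; {n_bad} entries <= 0")
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant features before Pareto scaling",
                    int(constant.sum()))
        logged = logged.loc[:, ~constant]
        sd = sd[~constant]
        table = table.select_features(logged.columns)
    scaled = (logged - logged.mean(axis=0)) / np.sqrt(sd)
    out = table.copy()
    out.values = scaled
    if report is not None:
        report.record("log_pareto", out)
    return out


def process(
    table: FeatureTable,
    min_rating: float = 5.0,
    min_rating_samples: int = 5,
    impute_trees: int = 100,
    impute_max_iter: int = 10,
    serrf_trees: int = 200,
    max_rsd_before: float = 50.0,
    max_rsd_after: float = 25.0,
    min_usable_fraction: float = 0.80,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, QcReport]:
    """Run the full stage chain.

    Returns ``(processed, normalized, report)`` where ``normalized`` is the
    median-normalized (pre-log) table used for direction-of-change and ratio
    analyses, and ``processed`` is the log/Pareto matrix used by the
    multivariate models.
    """
    report = QcReport()
    report.record("input", table)
    t = filter_by_peak_rating(table, min_rating, min_rating_samples, report)
    t = impute_missing(t, impute_trees, impute_max_iter, seed, report)
    t, report = qc_correct(t, n_trees=serrf_trees, seed=seed, report=report)
    t = rsd_filter(t, report, max_rsd_before, max_rsd_after)
    t = usable_hits_filter(t, min_usable_fraction, report)
    normalized = normalize_median(t, report=report)
    processed = log_pareto(normalized, report=report)
    return processed, normalized, report
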
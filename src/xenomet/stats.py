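"""Univariate tests and discriminant-feature selection.

Features are called discriminant by the conjunction of three criteria on a
CV-ANOVA-significant OPLS-DA model: VIP >= 1.5, |p(corr)| >= 0.50 and a
paired-t p-value <= 0.05.  No multiple-testing correction is applied by
default (the triple criterion is the filter); Benjamini-Hochberg is available
as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .oplsda import OplsDa, OplsDaResults

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # underflow guard for zero-variance nonzero differences


def _pair_arrays(values: pd.DataFrame, meta: pd.DataFrame,
                 group_a: str, group_b: str, pair_col: str):
    """Align group-b and group-a rows by pairing id; unpaired samples are
    dropped with a warning."""
    study = meta[meta["role"] == "study"] if "role" in meta else meta
    a = study[study["group"] == group_a]
    b = study[study["group"] == group_b]
    pairs = sorted(set(a[pair_col]) & set(b[pair_col]))
    dropped = (set(a[pair_col]) | set(b[pair_col])) - set(pairs)
    if dropped:
        log.warning("excluding unpaired pairing ids: %s", sorted(dropped))
    if not pairs:
        raise ValueError(f"no complete {group_b}/{group_a} pairs found")
    ia = [a.index[a[pair_col] == p][0] for p in pairs]
    ib = [b.index[b[pair_col] == p][0] for p in pairs]
    return values.loc[ib].to_numpy(float), values.loc[ia].to_numpy(float)


def paired_t_tests(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: str = "control",
    group_b: str = "exposed",
    pair_col: str = "pair_id",
    direction_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature paired t-test of group_b vs group_a.

    ``values`` is the processed matrix the test runs on (log scale by
    convention); ``direction_values`` optionally supplies a second matrix
    (normalized pre-log areas) from which the direction of change is read, so
    the reported arrow matches relative-concentration semantics.

    Returns a DataFrame indexed by feature with columns ``t``, ``pvalue``,
    ``mean_diff`` and ``direction`` ('up'/'down' in group_b).
    """
    B, A = _pair_arrays(values, meta, group_a, group_b, pair_col)
    diff = B - A
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_sd & (mean != 0), np.sign(mean) * np.inf, t)
    p = np.where(zero_sd & (mean != 0), _P_FLOOR, p)
    t = np.where(zero_sd & (mean == 0), 0.0, t)
    p = np.where(zero_sd & (mean == 0), 1.0, p)

    if direction_values is not None:
        Bd, Ad = _pair_arrays(direction_values, meta, group_a, group_b, pair_col)
        dmean = (Bd - Ad).mean(axis=0)
        dcols = direction_values.columns
        dmean = pd.Series(dmean, index=dcols).reindex(values.columns).to_numpy()
    else:
        dmean = mean
    direction = np.where(dmean > 0, "up", np.where(dmean < 0, "down", "none"))
    return pd.DataFrame(
        {"t": t, "pvalue": p, "mean_diff": mean, "direction": direction},
        index=values.columns,
    )


@dataclass(frozen=True)
class DiscriminantFeature:
    feature_id: str
    vip: float
    pcorr: float
    pvalue: float
    direction: str


def select_discriminant(
    results: OplsDaResults,
    tests: pd.DataFrame,
    vip_min: float = 1.5,
    pcorr_min: float = 0.50,
    p_max: float = 0.05,
    require_significant_model: bool = True,
    fdr: bool = False,
) -> tuple[list[DiscriminantFeature], str]:
    """Intersect the three selection criteria, sorted by VIP descending.

    Returns ``(features, status)``; a model that fails CV-ANOVA at 0.05 yields
    an empty list with status ``"model not significant"`` regardless of the
    per-feature statistics.  With ``fdr=True`` the univariate p-values are
    Benjamini-Hochberg adjusted before thresholding.
    """
    if require_significant_model and not results.significant:
        return [], "model not significant"
    pvals = tests["pvalue"].copy()
    if fdr:
        pvals = pd.Series(
            sps.false_discovery_control(pvals.to_numpy(), method="bh"),
            index=pvals.index,
        )
    common = results.vip.index.intersection(tests.index)
    picked = []
    for fid in common:
        v = float(results.vip[fid])
        pc = float(results.pcorr[fid])
        pv = float(pvals[fid])
        if v >= vip_min and abs(pc) >= pcorr_min and pv <= p_max:
            picked.append(
                DiscriminantFeature(
                    feature_id=str(fid), vip=v, pcorr=pc,
                    pvalue=float(tests.loc[fid, "pvalue"]),
                    direction=str(tests.loc[fid, "direction"]),
                )
            )
    picked.sort(key=lambda d: -d.vip)
    return picked, "ok"


def discriminant_frame(features: list[DiscriminantFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_id": f.feature_id, "VIP": f.vip, "p(corr)": f.pcorr,
             "P-value": f.pvalue, "Direction": f.direction}
            for f in features
        ]
    )


def exclude_and_refit(
    model: OplsDa,
    exclude: list[str],
    **fit_kws,
) -> tuple[OplsDaResults, OplsDaResults]:
    """Refit after removing an exclusion list of features (e.g. parent-drug
    biotransformation products that dominate the model).

    Returns ``(original_results, reduced_results)`` for side-by-side
    comparison.
    """
    exclude_set = {str(f) for f in exclude}
    unknown = exclude_set - set(model.feature_names)
    if unknown:
        raise ValueError(f"exclusion list contains unknown features: {sorted(unknown)}")
    keep = [i for i, f in enumerate(model.feature_names) if f not in exclude_set]
    if not keep:
        raise ValueError("exclusion list removes every feature")
    reduced = OplsDa(
        model.X[:, keep],
        model.y,
        feature_names=[model.feature_names[i] for i in keep],
        n_folds=model.n_folds,
        cv_seed=model.cv_seed,
    )
    return model.fit(**fit_kws), reduced.fit(**fit_kws)


def amino_acid_ratio_tests(
    values_normalized: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: list[tuple[str, str]],
    group_a: str = "control",
    group_b: str = "exposed",
    pair_col: str = "pair_id",
) -> pd.DataFrame:
    """Paired t-tests on log metabolite ratios (e.g. arginine/ornithine).

    Ratios are computed per sample on normalized (pre-log) areas, so any
    remaining global sample scaling cancels; missing ratio members are skipped
    with a warning.
    """
    rows = []
    for num, den in pairs:
        num, den = str(num), str(den)
        if num not in values_normalized or den not in values_normalized:
            log.warning("ratio %s/%s skipped: member feature missing", num, den)
            continue
        ratio = np.log(values_normalized[num] / values_normalized[den])
        frame = ratio.to_frame(name=f"{num}/{den}")
        res = paired_t_tests(frame, meta, group_a, group_b, pair_col)
        row = res.iloc[0]
        rows.append(
            {"ratio": f"{num}/{den}", "t": row["t"], "pvalue": row["pvalue"],
             "direction": row["direction"]}
        )
    return pd.DataFrame(rows)
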
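"""Synthetic untargeted LC-HRMS study generator with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a two-group (exposed/control), two-timepoint, quadruplicate cell-culture
  design plus pooled-QC injections (a lead-in block then every eighth
  injection) and three solvent- and medium-control samples;
* log-normal baseline peak areas with multiplicative injection-order drift
  applied to every sample including QCs;
* a stated fraction of truly differential features with stated log2 effects,
  injected on the log scale *before* drift so drift correction and
  differential analysis stay separable failure modes;
* intensity-dependent missingness (censoring probability rising as intensity
  falls below a threshold);
* a vendor-style peak rating fabricated as a saturating function of a
  signal-to-noise proxy;
* optionally, a spiked parent-compound biotransformation series at exact
  theoretical m/z, present only in exposed samples, with MS2 spectra whose
  fragment sets overlap within the family so molecular networking can recover
  it.

Everything is bit-reproducible for a given config seed, and the emitted
:class:`GroundTruth` records which features are differential and which are
spikes — the recovery-testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_TRANSFORMATIONS,
    ElementalFormula,
    Transformation,
    ion_mz,
)
from .featuretable import FeatureTable
from .msms import Ms2Spectrum

#: default biotransformation chains for the spiked series: one entry per
#: product feature; repeated formulas model positional isomers resolved only
#: by retention time.  17 products of the pyridine-alkaloid parent.
DEFAULT_SPIKE_CHAINS: list[tuple[str, ...]] = [
    ("demethylation",),                                   # nor-parent
    ("demethylation", "oxidation"),                       # 3a
    ("demethylation", "oxidation"),                       # 3b (isomer)
    ("demethylation", "oxidation"),                       # 3c (isomer)
    ("desaturation", "oxidation"),                        # lactam (major)
    ("oxidation",),                                       # 5a
    ("oxidation",),                                       # 5b (isomer)
    ("oxidation",),                                       # 5c (N-oxide)
    ("deamination to keto acid",),                        # 6
    ("deamination to hydroxy acid",),                     # 7
    ("desaturation", "di-oxidation"),                     # 8a
    ("desaturation", "di-oxidation"),                     # 8b (isomer)
    ("desaturation", "di-oxidation"),                     # 8c (isomer)
    ("di-oxidation",),                                    # 9a
    ("di-oxidation",),                                    # 9b (isomer)
    ("glycine conjugation",),                             # 10
    ("oxidation", "acetylation"),                         # 11
]


@dataclass(frozen=True)
class StudyDesignConfig:
    """The stated world: design counts, effect structure and noise models."""

    groups: tuple[str, str] = ("control", "exposed")
    timepoints: tuple[str, ...] = ("t1", "t4")
    replicates: int = 4
    qc_lead_in: int = 6          # QC injections before the first study sample
    qc_every: int = 8            # a QC every n-th injection thereafter
    n_blank: int = 3             # solvent controls
    n_medium: int = 3            # medium controls
    n_features: int = 300
    fraction_differential: float = 0.10
    log2_effect: float = 1.0     # per-timepoint effect size of true positives
    baseline_log_mean: float = np.log(1.0e6)
    baseline_log_sd: float = 1.5          # between-feature spread
    biological_cv: float = 0.25           # between-replicate (lognormal sd of ln)
    analytical_cv: float = 0.06           # QC / injection repeatability
    drift_amplitude: float = 0.0          # 0.5 -> factor 0.5..1.5 across run
    drift_shape: str = "linear"           # or "exponential"
    censor_quantile: float = 0.05         # censoring threshold as baseline quantile
    censor_width: float = 0.8             # logistic width on the log scale
    rating_midpoint_quantile: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.fraction_differential <= 1:
            raise ValueError("fraction_differential must be in [0, 1]")
        if self.replicates < 2 or self.n_features < 10:
            raise ValueError("need >= 2 replicates and >= 10 features")
        if int(self.fraction_differential * self.n_features) > self.n_features:
            raise ValueError("more differential than total features")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    differential: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: feature_id, timepoint, log2_effect, sign
    spikes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: feature_id, product_formula, chain, ion, expected_mz, rt
    drift: pd.DataFrame | None = None  # per-sample drift factor

    @property
    def differential_ids(self) -> set[str]:
        if self.differential.empty:
            return set()
        return set(self.differential["feature_id"].astype(str))

    @property
    def spike_ids(self) -> set[str]:
        if self.spikes.empty:
            return set()
        return set(self.spikes["feature_id"].astype(str))


def _injection_sequence(cfg: StudyDesignConfig, rng: np.random.Generator):
    """Sample ids, roles and injection order: QC lead-in, then randomized
    study/control samples with a QC every ``qc_every`` injections."""
    study = []
    for tp in cfg.timepoints:
        for grp in cfg.groups:
            for rep in range(1, cfg.replicates + 1):
                study.append(
                    (f"{grp}_{tp}_r{rep}", "study", grp, tp, f"{tp}_r{rep}")
                )
    others = [(f"solvent_{i+1}", "solvent_control", "none", "none", "")
              for i in range(cfg.n_blank)]
    others += [(f"medium_{i+1}", "medium_control", "none", "none", "")
               for i in range(cfg.n_medium)]
    run = study + others
    order = rng.permutation(len(run))
    run = [run[i] for i in order]

    rows = []
    inj = 1
    for i in range(cfg.qc_lead_in):
        rows.append((f"qc_{i+1}", "qc", "none", "none", "", inj))
        inj += 1
    qc_n = cfg.qc_lead_in
    since_qc = 0
    for rec in run:
        if since_qc == cfg.qc_every - 1:
            qc_n += 1
            rows.append((f"qc_{qc_n}", "qc", "none", "none", "", inj))
            inj += 1
            since_qc = 0
        rows.append((*rec, inj))
        inj += 1
        since_qc += 1
    qc_n += 1
    rows.append((f"qc_{qc_n}", "qc", "none", "none", "", inj))  # closing QC
    meta = pd.DataFrame(
        rows, columns=["sample_id", "role", "group", "timepoint", "pair_id",
                       "injection_order"]
    ).set_index("sample_id")
    return meta


def _drift_factor(order: np.ndarray, cfg: StudyDesignConfig) -> np.ndarray:
    if cfg.drift_amplitude == 0:
        return np.ones_like(order, dtype=float)
    x = (order - order.min()) / max(order.max() - order.min(), 1)
    if cfg.drift_shape == "exponential":
        shape = (np.exp(2 * x) - 1) / (np.e**2 - 1)
    else:
        shape = x
    return 1.0 - cfg.drift_amplitude + 2.0 * cfg.drift_amplitude * shape


def generate_feature_table(
    cfg: StudyDesignConfig,
) -> tuple[FeatureTable, GroundTruth]:
    """Generate a study feature table and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    meta = _injection_sequence(cfg, rng)
    n_samples = len(meta)
    p = cfg.n_features

    base_log = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, p)
    mz = np.round(rng.uniform(70.0, 850.0, p), 5)
    rt = np.round(rng.uniform(0.5, 30.0, p), 3)
    polarity = rng.choice(["pos", "neg"], p, p=[0.7, 0.3])
    feature_meta = pd.DataFrame(
        {
            "mz": mz, "rt": rt,
            "ion": np.where(polarity == "pos", "[M+H]+", "[M-H]-"),
            "polarity": polarity,
        },
        index=[f"F{i:05d}" for i in range(p)],
    )

    n_diff = int(round(cfg.fraction_differential * p))
    diff_idx = rng.choice(p, n_diff, replace=False)
    signs = rng.choice([-1.0, 1.0], n_diff)

    ln2 = np.log(2.0)
    log_x = np.tile(base_log, (n_samples, 1))

    # biological replicate variation for study & control-material samples;
    # QCs are a pooled aliquot, so they share one draw per feature
    role = meta["role"].to_numpy()
    is_qc = role == "qc"
    bio = rng.normal(0.0, cfg.biological_cv, (n_samples, p))
    bio[is_qc] = rng.normal(0.0, cfg.biological_cv, p)[None, :]  # shared pool
    log_x += bio

    # planted group x timepoint effects (exposed vs control), on log scale
    truth_rows = []
    grp = meta["group"].to_numpy()
    tp = meta["timepoint"].to_numpy()
    for j, s in zip(diff_idx, signs):
        for t in cfg.timepoints:
            mask = (grp == cfg.groups[1]) & (tp == t)
            log_x[mask, j] += s * cfg.log2_effect * ln2
            truth_rows.append(
                {"feature_id": feature_meta.index[j], "timepoint": t,
                 "log2_effect": cfg.log2_effect, "sign": int(s)}
            )

    # analytical noise on every injection
    log_x += rng.normal(0.0, cfg.analytical_cv, (n_samples, p))

    # multiplicative injection-order drift, all samples including QCs
    order = meta["injection_order"].to_numpy(float)
    drift = _drift_factor(order, cfg)
    x = np.exp(log_x) * drift[:, None]

    # censoring: missingness probability rises as intensity falls below the
    # threshold (logistic in log intensity); quantile 0 disables censoring
    if cfg.censor_quantile > 0:
        thresh = np.quantile(np.exp(base_log), cfg.censor_quantile)
        with np.errstate(over="ignore"):
            p_miss = 1.0 / (1.0 + np.exp((np.log(x) - np.log(thresh))
                                         / cfg.censor_width))
        missing = rng.uniform(size=x.shape) < p_miss
    else:
        missing = np.zeros(x.shape, bool)

    # vendor-style peak rating: saturating in S/N proxy, noisy
    k = np.quantile(x, cfg.rating_midpoint_quantile)
    rating = 10.0 * x / (x + k) + rng.normal(0.0, 0.4, x.shape)
    rating = np.clip(rating, 0.0, 10.0)
    rating[missing] = np.nan

    values = pd.DataFrame(x, index=meta.index, columns=feature_meta.index)
    values[missing] = np.nan
    detected = pd.DataFrame(~missing, index=meta.index,
                            columns=feature_meta.index)
    ratings = pd.DataFrame(rating, index=meta.index,
                           columns=feature_meta.index)

    table = FeatureTable(values, meta, feature_meta, ratings, detected)
    truth = GroundTruth(
        differential=pd.DataFrame(truth_rows),
        drift=pd.DataFrame({"injection_order": order, "factor": drift},
                           index=meta.index),
    )
    return table, truth


def spike_biotransformation_series(
    table: FeatureTable,
    truth: GroundTruth,
    parent: ElementalFormula | str = "C10H14N2",
    chains: list[tuple[str, ...]] | None = None,
    ion: str = "[M+H]+",
    abundance_profile: dict[int, float] | None = None,
    ppm_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, GroundTruth]:
    """Add one feature per biotransformation product at its exact theoretical
    m/z, detected in exposed samples only.

    ``chains`` is an ordered list of transformation-name tuples (one feature
    each; repeated product formulas represent positional isomers and get
    distinct retention times).  ``abundance_profile`` maps chain index ->
    relative abundance (default: the lactam product, index 4, dominates).
    ``ppm_jitter`` adds a uniform +-jitter to the stored m/z.
    """
    if isinstance(parent, str):
        parent = ElementalFormula(parent)
    chains = DEFAULT_SPIKE_CHAINS if chains is None else chains
    tmap = {t.name: t for t in DEFAULT_TRANSFORMATIONS}
    rng = np.random.default_rng(seed)
    if abundance_profile is None:
        abundance_profile = {i: 1.0 for i in range(len(chains))}
        abundance_profile[4 if len(chains) > 4 else 0] = 10.0  # major product

    meta = table.sample_meta
    exposed = ((meta["role"] == "study") & (meta["group"] == "exposed")).to_numpy()
    qc = (meta["role"] == "qc").to_numpy()
    existing_mz = table.feature_meta["mz"].to_numpy()

    new_cols, new_meta, new_rating, new_detect, spike_rows = {}, [], [], [], []
    for i, chain in enumerate(chains):
        formula = parent
        for name in chain:
            nxt = tmap[name].apply(formula)
            if nxt is None:
                raise ValueError(f"chain {chain} not applicable to {parent}")
            formula = nxt
        theo = ion_mz(formula, ion)
        obs = theo * (1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
        if np.any(np.abs(obs - existing_mz) / existing_mz < 1e-6):
            obs *= 1.0 + 2e-6  # nudge off a collision, logged by caller
        fid = f"BT{i:02d}"
        rt = float(np.round(rng.uniform(4.0, 22.0), 3))
        level = abundance_profile.get(i, 1.0) * 5.0e5
        col = np.full(table.n_samples, np.nan)
        col[exposed] = level * np.exp(rng.normal(0, 0.2, exposed.sum()))
        col[qc] = level * 0.5 * np.exp(rng.normal(0, 0.05, qc.sum()))
        new_cols[fid] = col
        new_meta.append({"mz": obs, "rt": rt, "ion": ion, "polarity": "pos"})
        rat = np.where(np.isnan(col), np.nan, 8.0)
        new_rating.append(rat)
        new_detect.append(~np.isnan(col))
        spike_rows.append(
            {"feature_id": fid, "product_formula": str(formula),
             "chain": " > ".join(chain), "ion": ion, "expected_mz": theo,
             "observed_mz": obs, "rt": rt}
        )

    values = table.values.copy()
    for fid, col in new_cols.items():
        values[fid] = col
    fmeta = pd.concat(
        [table.feature_meta,
         pd.DataFrame(new_meta, index=list(new_cols))]
    )
    ratings = table.ratings.copy() if table.ratings is not None else None
    if ratings is not None:
        for fid, rat in zip(new_cols, new_rating):
            ratings[fid] = rat
    detected = table.detected.copy() if table.detected is not None else None
    if detected is not None:
        for fid, det in zip(new_cols, new_detect):
            detected[fid] = det

    out = FeatureTable(values, table.sample_meta.copy(), fmeta, ratings, detected)
    new_truth = GroundTruth(
        differential=truth.differential.copy(),
        spikes=pd.DataFrame(spike_rows),
        drift=truth.drift,
    )
    return out, new_truth


def generate_spectra(
    truth: GroundTruth,
    parent: ElementalFormula | str = "C10H14N2",
    ion: str = "[M+H]+",
    n_scaffold: int = 8,
    n_decoys: int = 0,
    shared_fraction: float = 0.7,
    seed: int = 0,
) -> list[Ms2Spectrum]:
    """MS2 spectra for the spiked series (plus the parent and optional decoys).

    Products share ``shared_fraction`` of the parent's scaffold fragments,
    shifted by the product-parent mass difference, so the molecular-network
    generator can recover the family; decoys get unrelated fragment sets.
    """
    if truth.spikes.empty:
        raise ValueError("ground truth has no spiked series")
    if isinstance(parent, str):
        parent = ElementalFormula(parent)
    rng = np.random.default_rng(seed)
    parent_mz = ion_mz(parent, ion)
    scaffold = np.sort(rng.uniform(55.0, parent_mz - 5.0, n_scaffold))
    scaffold_int = rng.uniform(20.0, 100.0, n_scaffold)

    spectra = [
        Ms2Spectrum("parent", parent_mz,
                    np.column_stack([scaffold, scaffold_int]))
    ]
    for _, row in truth.spikes.iterrows():
        shift = row["expected_mz"] - parent_mz
        n_shared = max(3, int(round(shared_fraction * n_scaffold)))
        keep = rng.choice(n_scaffold, n_shared, replace=False)
        frags = scaffold[keep] + shift
        inten = scaffold_int[keep] * rng.uniform(0.8, 1.2, n_shared)
        n_extra = int(rng.integers(1, 5))
        extra = rng.uniform(55.0, row["expected_mz"] - 5.0, n_extra)
        frags = np.concatenate([frags, extra])
        inten = np.concatenate([inten, rng.uniform(5.0, 40.0, n_extra)])
        ok = (frags > 0) & (frags < row["expected_mz"] + 1.0)
        spectra.append(
            Ms2Spectrum(str(row["feature_id"]), float(row["expected_mz"]),
                        np.column_stack([frags[ok], inten[ok]]),
                        rt=float(row["rt"]))
        )
    for d in range(n_decoys):
        prec = float(rng.uniform(120.0, 600.0))
        n_pk = int(rng.integers(5, 15))
        frags = np.sort(rng.uniform(50.0, prec - 5.0, n_pk))
        spectra.append(
            Ms2Spectrum(f"decoy_{d}", prec,
                        np.column_stack([frags, rng.uniform(5, 100, n_pk)]))
        )
    return spectra
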
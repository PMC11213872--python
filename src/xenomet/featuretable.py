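"""The sample x feature peak-area container every pipeline stage transforms.

Layout follows common metabolomics practice: a ``values`` DataFrame with
samples as rows and features as columns, plus two metadata frames.  Sample
metadata carries the study design (role, group, timepoint, replicate pairing,
injection order); feature metadata carries m/z, retention time, preferred ion
and polarity.  Optional per-sample peak ratings and a pre-imputation detection
mask ride along, because two filters (peak rating, usable hits) need them.

On-disk format is the wide CSV the field exchanges (features as rows, samples
as columns) with sidecar metadata CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_ROLES = ("qc", "study", "blank", "solvent_control", "medium_control")


@dataclass
class FeatureTable:
    values: pd.DataFrame            # samples x features, NaN = missing
    sample_meta: pd.DataFrame       # index: sample ids
    feature_meta: pd.DataFrame      # index: feature ids
    ratings: pd.DataFrame | None = None   # samples x features, peak rating 0-10
    detected: pd.DataFrame | None = None  # samples x features, bool, pre-imputation

    def __post_init__(self):
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        for frame in (self.values, self.ratings, self.detected,
                      self.sample_meta, self.feature_meta):
            if frame is not None:
                frame.index.name = None
                frame.columns.name = None
        self.sample_meta.index = self.sample_meta.index.astype(str)
        self.feature_meta.index = self.feature_meta.index.astype(str)
        if not self.values.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.index]
        if not self.values.columns.equals(pd.Index(self.feature_meta.index)):
            self.feature_meta = self.feature_meta.loc[self.values.columns]
        if "injection_order" in self.sample_meta:
            orders = self.sample_meta["injection_order"].dropna()
            if orders.duplicated().any():
                raise ValueError("injection order must be unique per sample")
        # Raw peak areas are non-negative; processed (log/Pareto) tables are
        # not, so positivity is enforced by the stages that require it.

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def mask(self, role: str) -> pd.Series:
        return self.sample_meta["role"] == role

    @property
    def qc_ids(self) -> list[str]:
        return list(self.values.index[self.mask("qc")])

    @property
    def study_ids(self) -> list[str]:
        return list(self.values.index[self.mask("study")])

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            None if self.ratings is None else self.ratings.copy(),
            None if self.detected is None else self.detected.copy(),
        )

    def select_features(self, keep) -> "FeatureTable":
        keep = [str(k) for k in keep]
        return FeatureTable(
            self.values[keep],
            self.sample_meta.copy(),
            self.feature_meta.loc[keep],
            None if self.ratings is None else self.ratings[keep],
            None if self.detected is None else self.detected[keep],
        )

    def select_samples(self, keep) -> "FeatureTable":
        keep = [str(k) for k in keep]
        return FeatureTable(
            self.values.loc[keep],
            self.sample_meta.loc[keep],
            self.feature_meta.copy(),
            None if self.ratings is None else self.ratings.loc[keep],
            None if self.detected is None else self.detected.loc[keep],
        )

    # -- I/O --------------------------------------------------------------
    def to_csv(self, prefix: str | Path) -> list[Path]:
        """Write <prefix>.csv (features x samples), <prefix>.samples.csv,
        <prefix>.features.csv and optional ratings/detected sidecars."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        written = []
        p = prefix.with_suffix(".csv")
        self.values.T.to_csv(p, index_label="feature_id")
        written.append(p)
        p = prefix.parent / f"{prefix.name}.samples.csv"
        self.sample_meta.to_csv(p, index_label="sample_id")
        written.append(p)
        p = prefix.parent / f"{prefix.name}.features.csv"
        self.feature_meta.to_csv(p, index_label="feature_id")
        written.append(p)
        if self.ratings is not None:
            p = prefix.parent / f"{prefix.name}.ratings.csv"
            self.ratings.T.to_csv(p, index_label="feature_id")
            written.append(p)
        if self.detected is not None:
            p = prefix.parent / f"{prefix.name}.detected.csv"
            self.detected.T.astype(int).to_csv(p, index_label="feature_id")
            written.append(p)
        return written

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "FeatureTable":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_suffix(".csv"), index_col="feature_id").T
        sample_meta = pd.read_csv(
            prefix.parent / f"{prefix.name}.samples.csv", index_col="sample_id"
        )
        if "pair_id" in sample_meta:  # empty pairing ids round-trip as ""
            sample_meta["pair_id"] = sample_meta["pair_id"].fillna("")
        feature_meta = pd.read_csv(
            prefix.parent / f"{prefix.name}.features.csv", index_col="feature_id"
        )
        ratings = detected = None
        rp = prefix.parent / f"{prefix.name}.ratings.csv"
        if rp.exists():
            ratings = pd.read_csv(rp, index_col="feature_id").T
        dp = prefix.parent / f"{prefix.name}.detected.csv"
        if dp.exists():
            detected = pd.read_csv(dp, index_col="feature_id").T.astype(bool)
        return cls(values, sample_meta, feature_meta, ratings, detected)


@dataclass
class QcReport:
    """Per-stage provenance: feature/sample counts, parameters, and per-feature
    QC RSD before/after drift correction."""

    stages: list[dict] = dc_field(default_factory=list)
    rsd_before: pd.Series | None = None
    rsd_after: pd.Series | None = None

    def record(self, stage: str, table: FeatureTable, **params) -> None:
        self.stages.append(
            {
                "stage": stage,
                "n_features": table.n_features,
                "n_samples": table.n_samples,
                "params": {k: _jsonable(v) for k, v in params.items()},
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {"stages": self.stages}
        if self.rsd_before is not None:
            payload["median_qc_rsd_before"] = float(self.rsd_before.median())
        if self.rsd_after is not None:
            payload["median_qc_rsd_after"] = float(self.rsd_after.median())
        Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature relative standard deviation (%) over QC injections.

    RSD = 100 x sd / mean, with ddof=1.  Features with zero mean get NaN.
    """
    qc = table.values.loc[table.mask("qc")]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.nan
    return rsd
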
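"""Shared fixtures: tiny hand-built tables and seeded synthetic scenarios.

Expensive scenario fixtures are session-scoped so the drift-correction and
recovery tests share one generation + processing pass.
"""

import numpy as np
import pandas as pd
import pytest

from xenomet import (
    FeatureTable,
    StudyDesignConfig,
    generate_feature_table,
)


def make_table(values, roles=None, orders=None, groups=None, timepoints=None,
               pairs=None, mz=None, rt=None, ratings=None, detected=None):
    """Construct a FeatureTable from a plain samples x features array."""
    values = pd.DataFrame(np.asarray(values, float))
    n, p = values.shape
    values.index = [f"s{i}" for i in range(n)]
    values.columns = [f"f{j}" for j in range(p)]
    meta = pd.DataFrame(
        {
            "role": roles or ["study"] * n,
            "group": groups or ["control"] * n,
            "timepoint": timepoints or ["t1"] * n,
            "pair_id": pairs or [""] * n,
            "injection_order": orders or list(range(1, n + 1)),
        },
        index=values.index,
    )
    fmeta = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 500, p),
            "rt": rt if rt is not None else np.linspace(1, 20, p),
            "ion": ["[M+H]+"] * p,
            "polarity": ["pos"] * p,
        },
        index=values.columns,
    )
    r = None if ratings is None else pd.DataFrame(
        np.asarray(ratings, float), index=values.index, columns=values.columns
    )
    d = None if detected is None else pd.DataFrame(
        np.asarray(detected, bool), index=values.index, columns=values.columns
    )
    return FeatureTable(values, meta, fmeta, r, d)


@pytest.fixture(scope="session")
def drift_scenario():
    """Seeded study with strong multiplicative drift (factor 0.5 -> 1.5)."""
    cfg = StudyDesignConfig(n_features=80, drift_amplitude=0.5, seed=7,
                            fraction_differential=0.0)
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def driftfree_scenario():
    """Same design with the drift amplitude set to zero."""
    cfg = StudyDesignConfig(n_features=80, drift_amplitude=0.0, seed=7,
                            fraction_differential=0.0)
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def effect_scenario():
    """Strong planted effects (8-fold), no drift — recovery testing."""
    cfg = StudyDesignConfig(n_features=100, drift_amplitude=0.0,
                            fraction_differential=0.10, log2_effect=3.0,
                            seed=11)
    return generate_feature_table(cfg)
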
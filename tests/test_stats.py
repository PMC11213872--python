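"""Paired tests, triple-criterion selection, exclusion refits and metabolite
ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xenomet import (
    OplsDa,
    amino_acid_ratio_tests,
    exclude_and_refit,
    paired_t_tests,
    select_discriminant,
)


def _paired_meta(n_pairs):
    idx = [f"c{i}" for i in range(n_pairs)] + [f"e{i}" for i in range(n_pairs)]
    return pd.DataFrame(
        {
            "role": ["study"] * 2 * n_pairs,
            "group": ["control"] * n_pairs + ["exposed"] * n_pairs,
            "timepoint": ["t1"] * 2 * n_pairs,
            "pair_id": [f"p{i}" for i in range(n_pairs)] * 2,
        },
        index=idx,
    )


class TestPairedT:
    def test_identical_pairs_p_one(self):
        meta = _paired_meta(4)
        x = np.tile(np.arange(1.0, 5.0)[:, None], (2, 3))
        res = paired_t_tests(pd.DataFrame(x, index=meta.index), meta)
        assert (res["t"] == 0).all()
        assert (res["pvalue"] == 1.0).all()

    def test_constant_difference_underflow_guard(self):
        meta = _paired_meta(4)
        ctl = np.ones((4, 2))
        exp = ctl + 2.0  # exact +2 shift, zero variance of differences
        res = paired_t_tests(
            pd.DataFrame(np.vstack([ctl, exp]), index=meta.index), meta
        )
        assert (res["pvalue"] < 1e-12).all()
        assert (res["direction"] == "up").all()

    def test_textbook_hand_computation(self):
        """n=4 toy differences (1, 2, 3, 2): t = 4.9, p from the t-table."""
        meta = _paired_meta(4)
        ctl = np.zeros((4, 1))
        exp = np.array([[1.0], [2.0], [3.0], [2.0]])
        res = paired_t_tests(
            pd.DataFrame(np.vstack([ctl, exp]), index=meta.index), meta
        )
        d = exp.ravel()
        t_hand = d.mean() / (d.std(ddof=1) / 2.0)
        p_hand = 2 * sps.t.sf(abs(t_hand), 3)
        assert res["t"].iloc[0] == pytest.approx(t_hand)
        assert res["pvalue"].iloc[0] == pytest.approx(p_hand)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(3)
        meta = _paired_meta(6)
        x = rng.normal(size=(12, 5))
        res = paired_t_tests(pd.DataFrame(x, index=meta.index), meta)
        ref = sps.ttest_rel(x[6:], x[:6])
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(res["pvalue"], ref.pvalue, rtol=1e-12)

    def test_unpaired_samples_excluded(self):
        meta = _paired_meta(4)
        meta.loc["e3", "pair_id"] = "orphan"
        x = np.arange(16.0).reshape(8, 2)
        res = paired_t_tests(pd.DataFrame(x, index=meta.index), meta)
        assert res.shape[0] == 2  # columns intact, pairs reduced internally

    def test_direction_from_separate_matrix(self):
        """Direction can come from pre-log areas even when the test runs on
        the processed scale."""
        meta = _paired_meta(4)
        rng = np.random.default_rng(5)
        proc = pd.DataFrame(rng.normal(size=(8, 1)), index=meta.index)
        raw = pd.DataFrame(
            np.vstack([np.ones((4, 1)), np.full((4, 1), 3.0)]), index=meta.index
        )
        res = paired_t_tests(proc, meta, direction_values=raw)
        assert res["direction"].iloc[0] == "up"


def _fitted_model(seed=0, n_pairs=4, p=20, effect=4.0, n_signal=3):
    rng = np.random.default_rng(seed)
    meta = _paired_meta(n_pairs)
    X = rng.normal(0, 1, (2 * n_pairs, p))
    X[n_pairs:, :n_signal] += effect
    frame = pd.DataFrame(X, index=meta.index,
                         columns=[f"f{j}" for j in range(p)])
    y = (meta["group"] == "exposed").astype(int).to_numpy()
    res = OplsDa(frame, y, cv_seed=seed).fit()
    tests = paired_t_tests(frame, meta)
    return res, tests


class TestSelectDiscriminant:
    def test_triple_criterion_conjunction(self):
        res, tests = _fitted_model()
        sel, status = select_discriminant(res, tests)
        assert status == "ok"
        ids = {d.feature_id for d in sel}
        assert ids == {"f0", "f1", "f2"}
        vips = [d.vip for d in sel]
        assert vips == sorted(vips, reverse=True)

    def test_vip_boundary_strictness(self):
        """VIP 1.49 fails the >= 1.5 cut however good the other stats."""
        res, tests = _fitted_model()
        res.vip.iloc[:] = 1.49
        sel, _ = select_discriminant(res, tests)
        assert sel == []

    def test_nonsignificant_model_empty(self):
        res, tests = _fitted_model()
        res.cv_anova_pvalue = 0.2
        sel, status = select_discriminant(res, tests)
        assert sel == [] and status == "model not significant"

    def test_fdr_option_more_conservative(self):
        res, tests = _fitted_model(effect=1.2, n_signal=8)
        plain, _ = select_discriminant(res, tests,
                                       require_significant_model=False)
        bh, _ = select_discriminant(res, tests, fdr=True,
                                    require_significant_model=False)
        assert len(bh) <= len(plain)


class TestExcludeRefit:
    def test_empty_exclusion_identical(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 15))
        X[4:, :3] += 3
        y = [0] * 4 + [1] * 4
        model = OplsDa(X, y, cv_seed=2)
        orig, red = exclude_and_refit(model, [])
        assert orig.q2 == red.q2 and orig.r2y == red.r2y

    def test_excluding_noise_leaves_q2(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 20))
        X[5:, :4] += 4
        y = [0] * 5 + [1] * 5
        model = OplsDa(X, y, cv_seed=3)
        orig, red = exclude_and_refit(model, [f"x{j}" for j in range(15, 20)])
        assert abs(orig.q2 - red.q2) < 0.05

    def test_excluding_only_signal_kills_model(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 12))
        X[4:, :2] += 5
        y = [0] * 4 + [1] * 4
        model = OplsDa(X, y, cv_seed=4)
        orig, red = exclude_and_refit(model, ["x0", "x1"])
        assert orig.significant
        assert red.cv_anova_pvalue > 0.05

    def test_unknown_feature_rejected(self):
        model = OplsDa(np.random.default_rng(0).normal(size=(6, 4)),
                       [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="nope"):
            exclude_and_refit(model, ["nope"])

    def test_excluding_everything_rejected(self):
        model = OplsDa(np.random.default_rng(0).normal(size=(6, 3)),
                       [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="every feature"):
            exclude_and_refit(model, ["x0", "x1", "x2"])


class TestAminoAcidRatios:
    def _values(self, n_pairs=4, shift=1.0, seed=0):
        rng = np.random.default_rng(seed)
        meta = _paired_meta(n_pairs)
        base = rng.lognormal(10, 0.1, (2 * n_pairs, 2))
        base[n_pairs:, 0] *= shift  # numerator shifted in exposed only
        return pd.DataFrame(base, index=meta.index,
                            columns=["num", "den"]), meta

    def test_self_ratio_p_one(self):
        vals, meta = self._values()
        res = amino_acid_ratio_tests(vals, meta, [("num", "num")])
        assert res["pvalue"].iloc[0] == 1.0

    def test_twofold_shift_significant(self):
        vals, meta = self._values(shift=2.0)
        res = amino_acid_ratio_tests(vals, meta, [("num", "den")])
        assert res["pvalue"].iloc[0] < 0.05
        assert res["direction"].iloc[0] == "up"

    def test_invariant_to_sample_scaling(self):
        vals, meta = self._values(shift=2.0, seed=3)
        res1 = amino_acid_ratio_tests(vals, meta, [("num", "den")])
        scaled = vals.mul(
            pd.Series(np.linspace(0.5, 2.0, len(vals)), index=vals.index),
            axis=0,
        )
        res2 = amino_acid_ratio_tests(scaled, meta, [("num", "den")])
        assert res1["pvalue"].iloc[0] == pytest.approx(res2["pvalue"].iloc[0])

    def test_missing_member_skipped(self):
        vals, meta = self._values()
        res = amino_acid_ratio_tests(vals, meta, [("num", "absent")])
        assert res.empty
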
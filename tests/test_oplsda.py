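"""OPLS-DA model: oracle equivalence with plain PLS, VIP/p(corr) identities,
Q2 behaviour and CV-ANOVA calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xenomet import OplsDa, Pca, cv_anova_from_press
from xenomet.oplsda import _fit_opls, _folds


def nipals_pls1(X, y, tol=1e-12, max_iter=500):
    """Independent single-component NIPALS PLS1 oracle.

    Returns (x_mean, y_mean, w, p, c): predictions for new x are
    ((x - x_mean) - 0) @ w * c + y_mean after the usual deflation-free
    single-component evaluation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    u = yc.copy()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = Xc.T @ u / (u @ u)
        w_new = w_new / np.linalg.norm(w_new)
        t = Xc @ w_new
        c = yc @ t / (t @ t)
        u_new = yc * c / (c * c)
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u_new
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    c = yc @ t / (t @ t)
    return x_mean, y_mean, w, p, c


class TestOracleEquivalence:
    def test_zero_orth_equals_nipals_pls1_20_matrices(self):
        """With no orthogonal components the model is exactly a 1-component
        PLS-DA: predictions agree with an independent NIPALS implementation
        to 1e-8 on 20 random 8x10 matrices."""
        rng = np.random.default_rng(123)
        for rep in range(20):
            X = rng.normal(size=(8, 10))
            y = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
            fit = _fit_opls(X, y, n_orth=0)
            xm, ym, w, p, c = nipals_pls1(X, y)
            Xnew = rng.normal(size=(5, 10))
            ours, _ = fit.predict(Xnew)
            oracle = (Xnew - xm) @ w * c + ym
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(16, 12))
        X[:8] += 1.5
        y = np.array([0] * 8 + [1] * 8, float)
        fit = _fit_opls(X, y, n_orth=2)
        yc = y - y.mean()
        for k in range(fit.T_o.shape[1]):
            assert abs(fit.T_o[:, k] @ yc) < 1e-8


class TestFitBehaviour:
    def _strong(self, seed=0, n=8, p=30, effect=3.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        y = np.array([0] * (n // 2) + [1] * (n // 2), float)
        X[y == 1, :5] += effect
        return X, y

    def test_separated_classes_high_r2y(self):
        X, y = self._strong()
        res = OplsDa(X, y, cv_seed=1).fit()
        assert res.r2y > 0.95
        assert res.q2 > 0.5
        assert res.significant

    def test_components_string(self):
        X, y = self._strong()
        res = OplsDa(X, y, cv_seed=1).fit(n_orthogonal=2)
        assert res.components == "1 + 2"
        assert res.scores.shape == (8, 3)

    def test_q2_le_r2y(self):
        for seed in range(5):
            X, y = self._strong(seed=seed, effect=1.0)
            res = OplsDa(X, y, cv_seed=seed).fit()
            assert res.q2 <= res.r2y + 1e-12

    def test_permuted_labels_low_q2(self):
        """Random labels should almost never cross-validate."""
        X, y = self._strong(seed=3)
        rng = np.random.default_rng(42)
        low = 0
        for _ in range(100):
            yp = rng.permutation(y)
            if len(np.unique(yp[:4])) == 1:  # keep both classes in each half
                yp = y.copy()
            res = OplsDa(X, yp, cv_seed=0).fit(n_orthogonal=0)
            low += res.q2 <= 0.2
        assert low >= 95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            OplsDa(np.ones((6, 3)), [1, 1, 1, 1, 1, 1])

    def test_deterministic_given_seed(self):
        X, y = self._strong(seed=9)
        a = OplsDa(X, y, cv_seed=5).fit()
        b = OplsDa(X, y, cv_seed=5).fit()
        assert a.q2 == b.q2 and a.cv_anova_pvalue == b.cv_anova_pvalue


class TestVip:
    def test_mean_square_one_any_fit(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            X = rng.normal(size=(10, 25))
            y = np.array([0] * 5 + [1] * 5, float)
            res = OplsDa(X, y, cv_seed=seed).fit(n_orthogonal=0)
            assert float((res.vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_equal_weights_give_unit_vip(self):
        """All features identical to y: weights equal, every VIP = 1."""
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.tile(y[:, None], (1, 8)) + 0.0
        res = OplsDa(X, y, cv_seed=0).fit(n_orthogonal=0)
        np.testing.assert_allclose(res.vip.to_numpy(), 1.0, atol=1e-9)

    def test_single_informative_feature_max_vip(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0, 0.05, (8, 20))
        y = np.array([0] * 4 + [1] * 4, float)
        X[:, 7] = y * 4 + rng.normal(0, 0.05, 8)
        res = OplsDa(X, y, cv_seed=0).fit(n_orthogonal=0)
        assert res.vip.idxmax() == "x7"
        assert res.vip["x7"] > 1.5


class TestPcorr:
    def test_feature_equal_to_scores(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 6))
        y = np.array([0] * 5 + [1] * 5, float)
        res = OplsDa(X, y, cv_seed=0).fit(n_orthogonal=0)
        t = res.scores["t"].to_numpy()
        X2 = np.column_stack([X, t, -t])
        res2 = OplsDa(X2, y, cv_seed=0).fit(n_orthogonal=0)
        # correlation with its own score vector is +-1 up to refit wobble
        assert res2.pcorr.iloc[-2] > 0.99
        assert res2.pcorr.iloc[-1] < -0.99

    def test_bounded(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(8, 40))
        y = np.array([0] * 4 + [1] * 4, float)
        res = OplsDa(X, y, cv_seed=0).fit()
        assert res.pcorr.abs().max() <= 1.0

    def test_null_features_rarely_extreme(self):
        """Independent noise at n=8: |p(corr)| < 0.9 nearly always."""
        rng = np.random.default_rng(23)
        y = np.array([0] * 4 + [1] * 4, float)
        extremes = 0
        total = 0
        for _ in range(50):
            X = rng.normal(size=(8, 40))
            res = OplsDa(X, y, cv_seed=0).fit(n_orthogonal=0)
            extremes += int((res.pcorr.abs() >= 0.9).sum())
            total += 40
        assert extremes / total < 0.01


class TestCvAnova:
    def test_closed_form_oracle(self):
        """Hand-built residual table: F and p match a direct scipy F-tail."""
        press, ss, n, a = 1.7, 6.3, 16, 2
        f, p = cv_anova_from_press(press, ss, n, a)
        f_expected = ((ss - press) / a) / (press / (n - 1 - a))
        assert f == pytest.approx(f_expected)
        assert p == pytest.approx(float(sps.f.sf(f_expected, a, n - 1 - a)))

    def test_press_above_total_not_significant(self):
        f, p = cv_anova_from_press(10.0, 6.0, 16, 1)
        assert f == 0.0 and p == 1.0

    def test_perfect_prediction_limit(self):
        f, p = cv_anova_from_press(1e-12, 4.0, 16, 1)
        assert p < 1e-10

    def test_null_calibration_quick(self):
        """Pure-noise data: CV-ANOVA p > 0.05 in >= 90% of seeded replicates
        (the full 400-permutation calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(29)
        y = np.array([0] * 4 + [1] * 4, float)
        not_sig = 0
        for _ in range(100):
            X = rng.normal(size=(8, 30))
            res = OplsDa(X, y, cv_seed=0).fit()
            not_sig += res.cv_anova_pvalue > 0.05
        assert not_sig >= 90


class TestPca:
    def test_rank1_explains_everything(self):
        u = np.outer(np.arange(1.0, 7.0), np.array([1.0, 2.0, 3.0]))
        res = Pca(u, n_components=3).fit()
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(31)
        res = Pca(rng.normal(size=(12, 6)), n_components=4).fit()
        s = res.scores.to_numpy()
        off = s.T @ s - np.diag(np.diag(s.T @ s))
        assert np.abs(off).max() < 1e-8

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(37)
        res = Pca(rng.normal(size=(15, 8)), n_components=5).fit()
        ev = res.explained_variance_ratio
        assert all(a >= b - 1e-12 for a, b in zip(ev, ev[1:]))

    def test_qc_cluster_tighter_than_groups(self, effect_scenario):
        """In a processed study, QC pools sit closer together in PC space
        than the exposed/control centroids."""
        from xenomet.pipeline import process

        table, _ = effect_scenario
        processed, _, _ = process(table, seed=0)
        res = Pca(processed.values, n_components=2).fit()
        meta = processed.sample_meta
        s = res.scores
        qc = s[(meta["role"] == "qc").to_numpy()]
        exp = s[((meta["group"] == "exposed") & (meta["role"] == "study")).to_numpy()]
        ctl = s[((meta["group"] == "control") & (meta["role"] == "study")).to_numpy()]
        qc_spread = np.linalg.norm(qc - qc.mean(axis=0), axis=1).mean()
        sep = np.linalg.norm(exp.mean(axis=0) - ctl.mean(axis=0))
        assert qc_spread < sep


class TestFolds:
    def test_partition(self):
        folds = _folds(8, 7, seed=1)
        assert sorted(np.concatenate(folds)) == list(range(8))
        assert len(folds) == 7

    def test_reduced_when_small(self):
        assert len(_folds(4, 7, seed=0)) == 4
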
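"""Orthogonal PLS discriminant analysis (OPLS-DA) with VIP, p(corr), Q2 and
CV-ANOVA significance testing, plus a thin PCA front-end for data-quality
checks.

Model/Results layout
--------------------
``OplsDa(X, y)`` holds the data and cross-validation configuration;
``OplsDa.fit()`` returns an :class:`OplsDaResults` carrying scores, loadings,
cumulative R2X/R2Y/Q2, per-feature VIP and p(corr), the CV-ANOVA F-test, and a
``summary()`` table.

Algorithm
---------
The orthogonal signal correction follows the standard O-PLS scheme for a
single response: the predictive weight vector is ``w ∝ X'y``; each orthogonal
component removes from X the part of the loading ``p`` that is orthogonal to
``w`` (class-uncorrelated systematic variation), after which the single
predictive component is recomputed.  The number of orthogonal components K is
chosen by 7-fold cross-validation: components are added while each raises Q2
by more than ``dq2_min`` (default 0.01), capped at ``max_orthogonal``.  Models
are reported in the chemometrics convention "1 + K".

CV-ANOVA compares the cross-validated predictive residuals (PRESS) against
the corrected total sum of squares of y with an F statistic on
(A, N - 1 - A) degrees of freedom, A = 1 + K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["OplsDa", "OplsDaResults", "Pca", "PcaResults", "cv_anova_from_press"]


def _folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded permutation of the sample indices."""
    n_folds = min(n_folds, n)
    rng = np.random.default_rng(seed)
    return [f for f in np.array_split(rng.permutation(n), n_folds) if len(f)]


@dataclass
class _OplsFit:
    x_mean: np.ndarray
    y_mean: float
    w: np.ndarray                 # predictive weights, unit norm
    p: np.ndarray                 # predictive loadings
    c: float                      # y loading
    t: np.ndarray                 # predictive scores (train)
    W_o: np.ndarray               # orthogonal weights, p x K
    P_o: np.ndarray               # orthogonal loadings, p x K
    T_o: np.ndarray               # orthogonal scores, n x K
    r2x: float
    r2y: float

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (y_hat, t) for new observations."""
        Xc = np.asarray(X, float) - self.x_mean
        for k in range(self.W_o.shape[1]):
            t_o = Xc @ self.W_o[:, k]
            Xc = Xc - np.outer(t_o, self.P_o[:, k])
        t = Xc @ self.w
        return t * self.c + self.y_mean, t


def _fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int) -> _OplsFit:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    ss_x = float((Xc**2).sum())
    ss_y = float((yc**2).sum())

    wd = Xc.T @ yc
    nw = np.linalg.norm(wd)
    w = wd / nw if nw > 0 else wd

    W_o, P_o, T_o = [], [], []
    r2x_orth = 0.0
    for _ in range(n_orth):
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p = Xc.T @ t / tt
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o = w_o / n_o
        t_o = Xc @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o <= 0:
            break
        p_o = Xc.T @ t_o / tt_o
        Xc = Xc - np.outer(t_o, p_o)
        r2x_orth += tt_o * float(p_o @ p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = Xc @ w
    tt = float(t @ t)
    if tt > 0:
        p = Xc.T @ t / tt
        c = float(yc @ t / tt)
    else:
        p = np.zeros_like(w)
        c = 0.0
    resid = yc - t * c
    r2y = 1.0 - float(resid @ resid) / ss_y if ss_y > 0 else 0.0
    r2x = (tt * float(p @ p) + r2x_orth) / ss_x if ss_x > 0 else 0.0

    K = len(W_o)
    shape = (X.shape[1], K)
    return _OplsFit(
        x_mean=x_mean, y_mean=y_mean, w=w, p=p, c=c, t=t,
        W_o=np.column_stack(W_o) if K else np.zeros(shape),
        P_o=np.column_stack(P_o) if K else np.zeros(shape),
        T_o=np.column_stack(T_o) if K else np.zeros((X.shape[0], 0)),
        r2x=r2x, r2y=r2y,
    )


def _press(X: np.ndarray, y: np.ndarray, n_orth: int, folds) -> float:
    press = 0.0
    n = len(y)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        fit = _fit_opls(X[train], y[train], n_orth)
        y_hat, _ = fit.predict(X[test])
        press += float(((y[test] - y_hat) ** 2).sum())
    return press


def cv_anova_from_press(
    press: float, ss_total: float, n_samples: int, n_components: int
) -> tuple[float, float]:
    """CV-ANOVA F statistic and p-value.

    F = ((SS_total − PRESS)/A) / (PRESS/(N − 1 − A)) on (A, N − 1 − A)
    degrees of freedom, where SS_total is the corrected sum of squares of the
    response, PRESS the cross-validated predictive residual sum of squares and
    A the number of model components (predictive + orthogonal).  A model whose
    cross-validated predictions are no better than the class mean (PRESS >=
    SS_total) gets F = 0 and p = 1.
    """
    df2 = n_samples - 1 - n_components
    if press <= 0:
        return np.inf, 0.0
    if df2 <= 0:
        return 0.0, 1.0
    f = max(0.0, (ss_total - press) / n_components) / (press / df2)
    p = float(sps.f.sf(f, n_components, df2))
    return float(f), p


class OplsDa:
    """OPLS-DA model for a two-class comparison.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Processed (log/Pareto) data matrix, samples x features.
    y : (n,) array
        Class labels; any two distinct values (coded 0/1 internally).
    n_folds : int
        Cross-validation folds (7 by default, reduced to n when n < folds).
    cv_seed : int
        Seed for the contiguous-block fold assignment.
    """

    def __init__(self, X, y, feature_names=None, n_folds: int = 7, cv_seed: int = 0):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(float)
        self.X = np.asarray(X, float)
        if self.X.ndim != 2 or self.X.shape[1] == 0:
            raise ValueError("X must be a non-empty 2-D matrix")
        classes = pd.unique(pd.Series(y))
        if len(classes) != 2:
            raise ValueError(f"y must have exactly two classes, got {list(classes)}")
        counts = pd.Series(y).value_counts()
        if counts.min() < 3:
            raise ValueError("need >= 3 samples per class")
        self.classes_ = tuple(classes)
        self.y = (pd.Series(y).to_numpy() == classes[1]).astype(float)
        self.feature_names = (
            [str(f) for f in feature_names]
            if feature_names is not None
            else [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.n_folds = n_folds
        self.cv_seed = cv_seed

    @classmethod
    def from_feature_table(
        cls,
        table,
        group_a: str = "control",
        group_b: str = "exposed",
        timepoint: str | None = None,
        n_folds: int = 7,
        cv_seed: int = 0,
    ) -> "OplsDa":
        """Build a pairwise model from a processed :class:`FeatureTable`,
        keeping study samples of the two groups (optionally one timepoint)."""
        meta = table.sample_meta
        keep = (meta["role"] == "study") & meta["group"].isin([group_a, group_b])
        if timepoint is not None:
            keep &= meta["timepoint"] == timepoint
        sub = table.select_samples(table.values.index[keep])
        y = (sub.sample_meta["group"] == group_b).astype(int).to_numpy()
        return cls(sub.values, y, feature_names=sub.feature_ids,
                   n_folds=n_folds, cv_seed=cv_seed)

    # ------------------------------------------------------------------
    def fit(
        self,
        n_orthogonal: int | None = None,
        max_orthogonal: int = 3,
        dq2_min: float = 0.01,
    ) -> "OplsDaResults":
        """Fit the model.

        When ``n_orthogonal`` is None the orthogonal-component count is chosen
        by cross-validation (add while ΔQ2 > ``dq2_min``, up to
        ``max_orthogonal``); otherwise it is fixed.
        """
        X, y = self.X, self.y
        n = len(y)
        folds = _folds(n, self.n_folds, self.cv_seed)
        ss_y = float(((y - y.mean()) ** 2).sum())

        q2_path = []
        press_path = []

        def q2_at(k: int) -> float:
            press = _press(X, y, k, folds)
            press_path.append(press)
            q2 = 1.0 - press / ss_y if ss_y > 0 else 0.0
            q2_path.append(q2)
            return q2

        if n_orthogonal is None:
            k = 0
            q2 = q2_at(0)
            while k < max_orthogonal:
                q2_next = q2_at(k + 1)
                if q2_next - q2 > dq2_min:
                    k += 1
                    q2 = q2_next
                else:
                    q2_path.pop()
                    press_path.pop()
                    break
        else:
            k = int(n_orthogonal)
            for kk in range(k + 1):
                q2_at(kk)
            q2 = q2_path[-1]

        fit = _fit_opls(X, y, k)
        press = press_path[-1]
        a = 1 + k
        f_stat, p_cv = cv_anova_from_press(press, ss_y, n, a)

        # VIP over the single predictive component: with unit-norm weights,
        # VIP_j = sqrt(p) * |w_j|, hence mean(VIP^2) = 1.
        p_feat = X.shape[1]
        vip = np.sqrt(p_feat) * np.abs(fit.w)

        # p(corr): Pearson correlation of each processed feature with t.
        t = fit.t
        tc = t - t.mean()
        denom_t = np.sqrt(float(tc @ tc))
        Xc = X - X.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            pcorr = (Xc.T @ tc) / (sx * denom_t)
        pcorr = np.where(sx > 0, pcorr, 0.0)

        return OplsDaResults(
            model=self,
            _fit=fit,
            n_orthogonal=k,
            r2x=fit.r2x,
            r2y=fit.r2y,
            q2=q2,
            q2_path=tuple(q2_path),
            press=press,
            vip=pd.Series(vip, index=self.feature_names, name="VIP"),
            pcorr=pd.Series(np.clip(pcorr, -1, 1), index=self.feature_names,
                            name="p(corr)"),
            cv_anova_f=f_stat,
            cv_anova_pvalue=p_cv,
        )


@dataclass
class OplsDaResults:
    """Fitted OPLS-DA model: estimates, cross-validation statistics and
    per-feature influence measures."""

    model: OplsDa
    _fit: _OplsFit
    n_orthogonal: int
    r2x: float
    r2y: float
    q2: float
    q2_path: tuple
    press: float
    vip: pd.Series
    pcorr: pd.Series
    cv_anova_f: float
    cv_anova_pvalue: float

    @property
    def components(self) -> str:
        return f"1 + {self.n_orthogonal}"

    @property
    def significant(self) -> bool:
        return self.cv_anova_pvalue <= 0.05

    @property
    def scores(self) -> pd.DataFrame:
        cols = {"t": self._fit.t}
        for k in range(self.n_orthogonal):
            cols[f"t_orth{k + 1}"] = self._fit.T_o[:, k]
        return pd.DataFrame(cols)

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self._fit.w, index=self.model.feature_names, name="w")

    @property
    def loadings(self) -> pd.Series:
        return pd.Series(self._fit.p, index=self.model.feature_names, name="p")

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(float)
        y_hat, _ = self._fit.predict(np.asarray(X, float))
        return y_hat

    def summary(self) -> pd.DataFrame:
        """One-row model summary in the conventional report layout."""
        return pd.DataFrame(
            [
                {
                    "Components": self.components,
                    "R2X(cum)": round(self.r2x, 3),
                    "R2Y(cum)": round(self.r2y, 3),
                    "Q2(cum)": round(self.q2, 3),
                    "CV-ANOVA F": round(self.cv_anova_f, 3),
                    "CV-ANOVA P-value": self.cv_anova_pvalue,
                    "Significant": self.significant,
                }
            ]
        )

    def to_dict(self) -> dict:
        return {
            "components": self.components,
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "cv_anova_f": self.cv_anova_f,
            "cv_anova_pvalue": self.cv_anova_pvalue,
            "significant": bool(self.significant),
        }


class Pca:
    """Principal component analysis on a processed matrix (quality check)."""

    def __init__(self, X, n_components: int = 2):
        if isinstance(X, pd.DataFrame):
            self.index = list(X.index)
            X = X.to_numpy(float)
        else:
            self.index = list(range(len(X)))
        self.X = np.asarray(X, float)
        self.n_components = n_components

    def fit(self) -> "PcaResults":
        Xc = self.X - self.X.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        k = min(self.n_components, rank, *Xc.shape)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = u[:, :k] * s[:k]
        ss_tot = float((Xc**2).sum())
        evr = (s[:k] ** 2) / ss_tot if ss_tot > 0 else np.zeros(k)
        return PcaResults(
            scores=pd.DataFrame(
                scores, index=self.index,
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            loadings=vt[:k].T,
            explained_variance_ratio=evr,
        )


@dataclass
class PcaResults:
    scores: pd.DataFrame
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
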
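"""Partial least squares (NIPALS) with cross-validated component selection
and bootstrap BCa confidence intervals.

``NipalsPLS`` is a scikit-learn-compatible regressor implementing PLS1 by
the NIPALS algorithm with available-case inner products, so predictor cells
may be missing (NaN): every inner product skips missing terms and deflation
touches observed cells only.  Coefficients are reported on the standardized
scale (standard deviations of y per standard deviation of the predictor),
which makes them comparable across predictors with different units.

``bootstrap_bca`` computes bias-corrected and accelerated (BCa) intervals
for any vector-valued statistic of a case-resampled dataset: the bias
correction z0 comes from the fraction of bootstrap values below the point
estimate and the acceleration a from jackknife skewness.  When z0 is
infinite (the whole bootstrap distribution sits on one side of the point
estimate) the affected coordinate falls back to the percentile interval
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import RepeatedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("avidrivers")

__all__ = ["NipalsPLS", "PlsFit", "nipals_pls", "select_ncomp",
           "bootstrap_bca", "pls_with_bootstrap"]


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


class NipalsPLS(RegressorMixin, BaseEstimator):
    """PLS1 regression via NIPALS, tolerant of missing predictor cells.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract (>= 1, <= rank of X).

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Regression coefficients on the standardized (z-scored X and y)
        scale.
    intercept_ : float
        Intercept on the original response scale.
    x_weights_, x_loadings_ : ndarray of shape (p, n_components)
    y_loadings_ : ndarray of shape (n_components,)
    explained_variance_ : ndarray of shape (n_components,)
        Fraction of response variance captured by each component.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, names = _as_array(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 3:
            raise ValueError("PLS needs n >= 3 rows")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        obs = ~np.isnan(X)
        if (~obs).all(axis=0).any():
            j = int(np.flatnonzero((~obs).all(axis=0))[0])
            raise ValueError(f"column '{names[j]}' is entirely missing")
        mean = np.nanmean(X, axis=0)
        std = np.nanstd(X, axis=0, ddof=1)
        if (std == 0).any():
            j = int(np.flatnonzero(std == 0)[0])
            raise ValueError(f"column '{names[j]}' is constant")
        self.x_mean_, self.x_std_ = mean, std
        self.y_mean_, self.y_std_ = float(y.mean()), float(y.std(ddof=1))
        ysd = self.y_std_ if self.y_std_ > 0 else 1.0
        Xc = (X - mean) / std
        Xf = np.where(obs, Xc, 0.0)
        M = obs.astype(float)
        u = (y - self.y_mean_) / ysd
        y_var0 = float(u @ u)

        A = self.n_components
        W = np.zeros((p, A)); P = np.zeros((p, A)); Q = np.zeros(A)
        T = np.zeros((n, A)); evar = np.zeros(A)
        for a in range(A):
            denom_w = M.T @ (u * u)
            if not (denom_w > 0).all() or not np.any(u):
                A = a
                break
            w = (Xf.T @ u) / denom_w
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                A = a
                break
            w /= nw
            denom_t = M @ (w * w)
            t = (Xf @ w) / np.where(denom_t > 0, denom_t, 1.0)
            tt = float(t @ t)
            if tt < 1e-12:
                A = a
                break
            pl = (Xf.T @ t) / (M.T @ (t * t))
            q = float(u @ t) / tt
            Xf = Xf - M * np.outer(t, pl)
            u = u - q * t
            W[:, a], P[:, a], Q[a], T[:, a] = w, pl, q, t
            evar[a] = q * q * tt / y_var0 if y_var0 > 0 else 0.0
        if A == 0:
            # response orthogonal to all predictors: zero-coefficient model
            self.coef_ = np.zeros(p)
            self.n_components_ = 0
        else:
            W, P, Q = W[:, :A], P[:, :A], Q[:A]
            self.coef_ = W @ np.linalg.solve(P.T @ W, Q)
            self.n_components_ = A
        self.x_weights_ = W[:, :A] if A else np.zeros((p, 0))
        self.x_loadings_ = P[:, :A] if A else np.zeros((p, 0))
        self.y_loadings_ = Q[:A] if A else np.zeros(0)
        self.explained_variance_ = evar[:A]
        self.intercept_ = self.y_mean_
        self.feature_names_ = names
        self.n_features_in_ = p
        return self

    def _scores(self, X):
        """Component scores for new rows, available-case as in fitting."""
        Xc = (X - self.x_mean_) / self.x_std_
        obs = ~np.isnan(Xc)
        Xf = np.where(obs, Xc, 0.0)
        M = obs.astype(float)
        T = np.zeros((X.shape[0], self.n_components_))
        for a in range(self.n_components_):
            w = self.x_weights_[:, a]
            denom = M @ (w * w)
            t = (Xf @ w) / np.where(denom > 0, denom, 1.0)
            Xf = Xf - M * np.outer(t, self.x_loadings_[:, a])
            T[:, a] = t
        return T

    def predict(self, X, n_components: int | None = None):
        check_is_fitted(self, "coef_")
        X, _ = _as_array(X)
        A = self.n_components_ if n_components is None else min(n_components,
                                                                self.n_components_)
        T = self._scores(X)[:, :A]
        ysd = self.y_std_ if self.y_std_ > 0 else 1.0
        return self.y_mean_ + ysd * (T @ self.y_loadings_[:A])


@dataclass
class PlsFit:
    """Point estimates plus bootstrap intervals for a PLS regression."""

    n_comp: int
    predictors: list
    coef: np.ndarray            # standardized scale
    intercept: float
    ci_lo: np.ndarray = None
    ci_hi: np.ndarray = None
    significant: np.ndarray = None   # CI excludes 0
    explained_variance: np.ndarray = None
    n_boot: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {"predictor": self.predictors, "coef": self.coef}
        if self.ci_lo is not None:
            d.update(ci_lo=self.ci_lo, ci_hi=self.ci_hi,
                     significant=self.significant)
        return pd.DataFrame(d)


def nipals_pls(X, y, n_comp: int) -> PlsFit:
    """Point-estimate PLS fit (thin wrapper over :class:`NipalsPLS`)."""
    _, names = _as_array(X)
    est = NipalsPLS(n_components=n_comp).fit(X, y)
    return PlsFit(n_comp=est.n_components_, predictors=names, coef=est.coef_,
                  intercept=est.intercept_,
                  explained_variance=est.explained_variance_)


def select_ncomp(X, y, cv_folds: int = 5, cv_repeats: int = 10,
                 seed: int = 0, max_comp: int | None = None) -> int:
    """Cross-validated component count with a one-standard-error rule.

    Mean squared prediction error is estimated by repeated K-fold CV for
    every component count up to ``max_comp``; the selected count is the
    smallest one whose mean error is within one standard error of the
    minimum (ties resolved toward fewer components).
    """
    Xa, _ = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if n < cv_folds:
        raise ValueError(f"n = {n} < cv_folds = {cv_folds}")
    if max_comp is None:
        max_comp = max(1, min(p, n - int(np.ceil(n / cv_folds)) - 1))
    cv = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    errors = []   # one row per split: MSE per component count
    for train, test in cv.split(Xa):
        est = NipalsPLS(n_components=max_comp).fit(Xa[train], y[train])
        row = []
        for a in range(1, max_comp + 1):
            pred = est.predict(Xa[test], n_components=a)
            row.append(float(np.mean((y[test] - pred) ** 2)))
        errors.append(row)
    errors = np.asarray(errors)
    mean = errors.mean(axis=0)
    best = int(np.argmin(mean))
    # repeats of K-fold CV reuse the same rows, so the split errors are not
    # independent; scale fold-level spread by sqrt(K) only (conservative,
    # biases ties toward fewer components)
    se = errors[:, best].std(ddof=1) / np.sqrt(cv_folds)
    within = np.flatnonzero(mean <= mean[best] + se)
    return int(within[0]) + 1


def _bca_levels(p0: float, a: float, alpha: float):
    """Adjusted quantile levels (a1, a2) from bias fraction p0 and
    acceleration a.  With p0 = 0.5 (z0 = 0) and a = 0 this reduces exactly
    to the percentile levels (alpha/2, 1 - alpha/2)."""
    z0 = norm.ppf(p0)
    zlo, zhi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    a1 = norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
    a2 = norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
    return float(a1), float(a2)


def bootstrap_bca(statistic, data, B: int = 1000, alpha: float = 0.05,
                  seed: int = 0, max_failures: float = 0.1):
    """BCa confidence intervals for a statistic of a case-resampled dataset.

    ``data`` is an array or a tuple of arrays resampled jointly along axis
    0; ``statistic(data)`` returns a scalar or 1-d vector.  Returns
    ``(lo, hi, info)`` with per-coordinate bounds; ``info`` records z0, the
    acceleration and any percentile fallbacks.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    arrays = data if isinstance(data, tuple) else (data,)
    n = arrays[0].shape[0]
    def _take(idx):
        sub = tuple(a[idx] for a in arrays)
        return sub if isinstance(data, tuple) else sub[0]
    theta = np.atleast_1d(np.asarray(statistic(data), dtype=float))
    if not np.isfinite(theta).all():
        raise ValueError("statistic is not finite on the original data")
    rng = np.random.default_rng(seed)
    boots = np.empty((B, theta.size))
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            boots[b] = np.atleast_1d(statistic(_take(idx)))
        except Exception:
            failures += 1
            boots[b] = np.nan
            if failures > max_failures * B:
                raise RuntimeError(
                    f"statistic failed on more than {max_failures:.0%} of resamples")
    good = ~np.isnan(boots).any(axis=1)
    boots = boots[good]
    # jackknife acceleration
    jack = np.empty((n, theta.size))
    keep = np.arange(n)
    for i in range(n):
        jack[i] = np.atleast_1d(statistic(_take(np.delete(keep, i))))
    jm = jack.mean(axis=0)
    dev = jm - jack
    denom = (dev ** 2).sum(axis=0) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, (dev ** 3).sum(axis=0) / (6.0 * denom), 0.0)
    lo = np.empty(theta.size); hi = np.empty(theta.size)
    fallback = np.zeros(theta.size, dtype=bool)
    for k in range(theta.size):
        bk = boots[:, k]
        if bk.max() == bk.min():
            lo[k] = hi[k] = bk[0]
            continue
        p0 = np.mean(bk < theta[k])
        if p0 <= 0.0 or p0 >= 1.0:
            fallback[k] = True
            logger.warning("BCa z0 infinite for coordinate %d; "
                           "falling back to percentile interval", k)
            a1, a2 = alpha / 2, 1 - alpha / 2
        else:
            a1, a2 = _bca_levels(p0, a[k], alpha)
        lo[k] = np.quantile(bk, a1)
        hi[k] = np.quantile(bk, a2)
    info = {"acceleration": a, "fallback": fallback, "n_boot_used": int(good.sum())}
    return lo, hi, info


def pls_with_bootstrap(X, y, n_boot: int = 1000, alpha: float = 0.05,
                       cv_folds: int = 5, cv_repeats: int = 10,
                       seed: int = 0, n_comp: int | None = None) -> PlsFit:
    """PLS with CV-selected components and BCa-bootstrapped coefficients.

    Component count is selected by repeated cross-validation on the full
    data; coefficients are then case-resampled (rows of (X, y)) at that
    count and BCa intervals computed.  A predictor is flagged significant
    when its interval excludes zero.
    """
    Xa, names = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    if n_comp is None:
        n_comp = select_ncomp(Xa, y, cv_folds=cv_folds, cv_repeats=cv_repeats,
                              seed=seed)
    est = NipalsPLS(n_components=n_comp).fit(Xa, y)

    def stat(d):
        Xi, yi = d
        return NipalsPLS(n_components=n_comp).fit(Xi, yi).coef_

    lo, hi, _ = bootstrap_bca(stat, (Xa, y), B=n_boot, alpha=alpha, seed=seed)
    sig = (lo > 0) | (hi < 0)
    return PlsFit(n_comp=est.n_components_, predictors=names, coef=est.coef_,
                  intercept=est.intercept_, ci_lo=lo, ci_hi=hi, significant=sig,
                  explained_variance=est.explained_variance_, n_boot=n_boot)
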
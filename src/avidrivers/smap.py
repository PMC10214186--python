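"""Multivariate S-map: sequential locally weighted linear models whose
coefficients approximate Jacobian elements (interaction strengths).

For every target time t* a linear model predicting the target variable one
step ahead is fitted to all state vectors, each weighted by
``w_k = exp(-theta * ||x(t_k) - x(t*)|| / d_bar)`` with ``d_bar`` the mean
distance from x(t*) to the other states.  The weighted system B = A·C is
solved by SVD-based least squares (relative singular-value cutoff 1e-8), so
theta = 0 reproduces the global least-squares model at every t* and larger
theta makes the model increasingly local.  The reported forecast skill is a
separate leave-one-out pass (the target's own row receives weight zero).

Because every column is standardized per country before embedding, the
coefficients are in sd-per-sd units and comparable across pressures; their
temporal average, further averaged across countries, is the package's
per-(species, pressure) interaction strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["SmapFit", "PressureEffect", "BlockSpec", "smap_solve",
           "smap_skill_grid", "select_theta", "build_block",
           "aggregate_effects", "count_signed_effects", "SMapRegressor"]

SVD_RCOND = 1e-8


def _pearson(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _smap_batched(X, y, thetas, loo: bool):
    """Local linear fits for every target row, batched over theta.

    Returns ``(coeffs, preds, skills)`` where ``coeffs[i]`` has shape
    (n, p + 1) (intercept first) for ``thetas[i]`` and ``preds`` are the
    per-target predictions (leave-one-out when ``loo``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    D = cdist(X, X)
    dbar = D.sum(axis=1) / max(n - 1, 1)
    if not (dbar > 0).all():
        raise ValueError("degenerate state space: all states identical")
    coeffs_all, preds_all, skills = [], [], []
    for theta in thetas:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        W = np.exp(-theta * D / dbar[:, None])
        if loo:
            W = W.copy()
            np.fill_diagonal(W, 0.0)
        A = W[:, :, None] * Xa[None, :, :]          # (n, n, p+1)
        B = W * y[None, :]                          # (n, n)
        C = np.linalg.pinv(A, rcond=SVD_RCOND) @ B[:, :, None]
        C = C[:, :, 0]                              # (n, p+1)
        pred = (Xa * C).sum(axis=1)
        coeffs_all.append(C)
        preds_all.append(pred)
        skills.append(_pearson(pred, y))
    return coeffs_all, preds_all, np.asarray(skills)


def smap_weights(X, target_index: int, theta: float) -> np.ndarray:
    """Local-regression weights for one target state (exposed for testing).

    w_k = exp(-theta * d_k / d_bar) with d_bar the mean distance from the
    target to the other states; the target's own weight is 1.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    X = np.asarray(X, dtype=float)
    d = np.linalg.norm(X - X[target_index], axis=1)
    dbar = d.sum() / max(len(X) - 1, 1)
    if dbar == 0:
        raise ValueError("degenerate state space: all states identical")
    return np.exp(-theta * d / dbar)


@dataclass
class SmapFit:
    """S-map fit at a fixed theta for one block."""

    theta: float
    col_names: list
    coeffs_by_time: np.ndarray   # (n, p + 1): intercept, then partials
    mean_coeffs: np.ndarray      # (p,) temporal average of the partials
    intercept_mean: float
    skill: float                 # leave-one-out prediction rho
    n_obs: int


def smap_solve(X, y, theta: float, col_names=None, horizon_note: int = 1) -> SmapFit:
    """Fit the S-map at a single theta.

    ``X`` holds the embedded block columns at time t (target variable first
    by convention), ``y`` the target at t + 1; columns must be standardized
    upstream.  Coefficients per target time come from the all-rows weighted
    fit; the skill is leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"S-map needs >= E + 2 rows (got {n} for E = {p})")
    coeffs_list, _, _ = _smap_batched(X, y, [theta], loo=False)
    C = coeffs_list[0]
    _, _, loo_skills = _smap_batched(X, y, [theta], loo=True)
    skill = loo_skills[0]
    names = col_names if col_names is not None else [f"c{j}" for j in range(p)]
    return SmapFit(theta=float(theta), col_names=list(names),
                   coeffs_by_time=C, mean_coeffs=C[:, 1:].mean(axis=0),
                   intercept_mean=float(C[:, 0].mean()),
                   skill=float(skill), n_obs=n)


def smap_skill_grid(X, y, thetas):
    """Leave-one-out skill for each theta (shared distance computation)."""
    _, preds, skills = _smap_batched(X, y, list(thetas), loo=True)
    return skills, preds


def select_theta(X, y, grid=(0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0,
                             4.0, 6.0, 8.0, 10.0),
                 n_boot: int = 200, seed: int = 0) -> float:
    """Theta maximizing leave-one-out skill, with a plateau rule.

    Among thetas whose skill lies within one bootstrap standard deviation of
    the best skill, the smallest is returned — preferring the most global
    model guards against overweighting the states nearest each target.
    """
    grid = sorted(grid)
    if len(grid) < 5:
        raise ValueError("theta grid needs >= 5 points")
    if grid[0] < 0 or grid[-1] > 10:
        raise ValueError("theta grid must lie within [0, 10]")
    skills, preds = smap_skill_grid(X, y, grid)
    best = int(np.argmax(skills))
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    npairs = len(y)
    idx = rng.integers(0, npairs, size=(n_boot, npairs))
    pb = preds[best]
    rhos = np.array([_pearson(pb[i], y[i]) for i in idx])
    sd = rhos.std(ddof=1)
    ok = np.flatnonzero(skills >= skills[best] - sd)
    return float(grid[int(ok[0])])


@dataclass
class BlockSpec:
    """Embedded block for one species: per-segment design matrices."""

    col_names: list                # "species", pressure ids, "species_lag{k}"
    by_segment: dict               # segment -> (X rows x E, y)
    skipped: bool = False
    skip_reason: str = ""


def build_block(species_by_segment, pressures_by_segment: dict,
                ccm_results: dict, E: int, alpha: float = 0.05) -> BlockSpec:
    """Assemble the S-map block from CCM-selected pressures.

    Columns: the species series first, then the significant pressures in
    order of ascending CCM p-value (ties broken by descending skill at the
    largest library), truncated to E - 1; if fewer pressures are significant
    the remaining columns are lagged copies of the species series.  With no
    significant pressure the block is skipped and the species recorded as
    "no identified impact".
    """
    sig = [(pid, res) for pid, res in ccm_results.items()
           if res is not None and res.convergent]
    if not sig:
        return BlockSpec(col_names=[], by_segment={}, skipped=True,
                         skip_reason="no significant pressure")
    sig.sort(key=lambda pr: (pr[1].p_value, -pr[1].rho_by_L[-1]))
    selected = [pid for pid, _ in sig[:max(E - 1, 0)]]
    n_fill = max(E - 1 - len(selected), 0)
    col_names = ["species"] + selected + [f"species_lag{k}" for k in
                                          range(1, n_fill + 1)]
    by_segment = {}
    segments = range(len(species_by_segment))
    for s in segments:
        sp = np.asarray(species_by_segment[s], dtype=float)
        m = len(sp)
        t0 = n_fill
        ts = np.arange(t0, m - 1)
        if len(ts) == 0:
            continue
        cols = [sp[ts]]
        for pid in selected:
            cols.append(np.asarray(pressures_by_segment[pid][s], dtype=float)[ts])
        for k in range(1, n_fill + 1):
            cols.append(sp[ts - k])
        by_segment[s] = (np.column_stack(cols), sp[ts + 1])
    return BlockSpec(col_names=col_names, by_segment=by_segment)


@dataclass
class PressureEffect:
    """Country-averaged S-map interaction strength for one pair."""

    species: str
    pressure: str
    effect: float                # mean over countries of temporal-mean coeff
    n_countries: int
    sign: str                    # "negative" | "positive"
    significant: bool


def aggregate_effects(fits_by_country: dict, species_id: str,
                      ccm_results: dict | None = None, alpha: float = 0.05,
                      n_boot: int = 1000, seed: int = 0) -> list:
    """Average per-country S-map coefficients into per-pressure effects.

    With >= 3 countries, significance is a bootstrap percentile CI (over
    countries) of the mean excluding zero; with fewer countries it is
    inherited from the CCM significance of that pressure.
    """
    if not fits_by_country:
        return []
    col_names = next(iter(fits_by_country.values())).col_names
    rng = np.random.default_rng(seed)
    effects = []
    for j, name in enumerate(col_names):
        if name == "species" or name.startswith("species_lag"):
            continue
        vals = np.array([fit.mean_coeffs[j] for fit in
                         fits_by_country.values()])
        eff = float(vals.mean())
        nc = len(vals)
        if nc >= 3:
            idx = rng.integers(0, nc, size=(n_boot, nc))
            means = vals[idx].mean(axis=1)
            lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
            significant = bool(lo > 0 or hi < 0)
        else:
            res = (ccm_results or {}).get(name)
            significant = bool(res.convergent) if res is not None else False
        effects.append(PressureEffect(
            species=species_id, pressure=name, effect=eff, n_countries=nc,
            sign="negative" if eff < 0 else "positive", significant=significant))
    return effects


def count_signed_effects(effects, pressures=None) -> pd.DataFrame:
    """Per-pressure counts of species with negative / positive mean effects.

    Only species with an identified impact (i.e. present in ``effects``)
    are counted.
    """
    rows = {}
    for e in effects:
        d = rows.setdefault(e.pressure, {"n_negative": 0, "n_positive": 0})
        d["n_negative" if e.sign == "negative" else "n_positive"] += 1
    if pressures is not None:
        for p in pressures:
            rows.setdefault(p, {"n_negative": 0, "n_positive": 0})
    out = (pd.DataFrame.from_dict(rows, orient="index")
             .rename_axis("pressure").reset_index())
    if out.empty:
        out = pd.DataFrame(columns=["pressure", "n_negative", "n_positive"])
    out["n_total"] = out.get("n_negative", 0) + out.get("n_positive", 0)
    return out.sort_values("pressure").reset_index(drop=True)


class SMapRegressor:
    """Estimator-style S-map: fit() stores time-varying coefficients.

    Parameters: ``theta`` (nonlinearity; None selects it on the training
    block via :func:`select_theta`), ``theta_grid``, ``seed``.  Fitted
    attributes: ``theta_``, ``coeffs_by_time_``, ``mean_coeffs_``,
    ``skill_``.
    """

    def __init__(self, theta: float | None = None,
                 theta_grid=(0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0,
                             4.0, 6.0, 8.0, 10.0), seed: int = 0):
        self.theta = theta
        self.theta_grid = theta_grid
        self.seed = seed

    def get_params(self, deep=True):
        return {"theta": self.theta, "theta_grid": self.theta_grid,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        theta = self.theta
        if theta is None:
            theta = select_theta(X, y, grid=self.theta_grid, seed=self.seed)
        fit = smap_solve(X, y, theta)
        self.theta_ = fit.theta
        self.coeffs_by_time_ = fit.coeffs_by_time
        self.mean_coeffs_ = fit.mean_coeffs
        self.skill_ = fit.skill
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float).ravel()
        return self

    def predict(self, X):
        """Predict the target at t + 1 for new state vectors."""
        Xn = np.atleast_2d(np.asarray(X, dtype=float))
        Xa_tr = np.hstack([np.ones((len(self.X_), 1)), self.X_])
        D = cdist(Xn, self.X_)
        dbar = D.mean(axis=1)
        out = np.empty(len(Xn))
        for i in range(len(Xn)):
            w = np.exp(-self.theta_ * D[i] / dbar[i]) if dbar[i] > 0 else \
                np.ones(len(self.X_))
            A = w[:, None] * Xa_tr
            b = w * self.y_
            c, *_ = np.linalg.lstsq(A, b, rcond=SVD_RCOND)
            out[i] = np.concatenate([[1.0], Xn[i]]) @ c
        return out
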
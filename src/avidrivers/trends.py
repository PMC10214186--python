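"""Relative trends, supranational species indices and multispecies indices.

The *relative trend* of an annual series is the ordinary-least-squares slope
of value on year divided by the first observed value — a fractional change
per year.  Supranational species indices combine national index series by a
population-size-weighted geometric mean.  The multispecies index (MSI) is
the across-species geometric mean of rebased indices, with Monte Carlo
confidence bands obtained by resampling each species-year index from a
lognormal whose mean and sd match the reported index and standard error.

The MSI here is a geometric-mean index with lognormal Monte Carlo
uncertainty, not a state-space smoother: it preserves the meaning of the
composite index while staying fully specified by this module alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RelativeTrend:
    """OLS slope scaled by the first value, with propagated uncertainty."""

    slope_rel: float      # fraction of first value per year
    se: float             # same scaling applied to the OLS slope se
    period: tuple         # (first_year, last_year)
    percent_change: float  # slope_rel * (last - first) * 100

    def __post_init__(self):
        span = self.period[1] - self.period[0]
        assert abs(self.percent_change - self.slope_rel * span * 100.0) < 1e-9


def relative_trend(years, values) -> RelativeTrend:
    """Relative trend of an annual series (slope / first value).

    Requires at least three observed years and a non-zero first value; NaNs
    are dropped.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    years, values = years[keep], values[keep]
    order = np.argsort(years)
    years, values = years[order], values[order]
    if len(years) < 3:
        raise ValueError("relative_trend needs >= 3 observed years")
    first = values[0]
    if first == 0:
        raise ValueError("first value is 0; relative trend undefined")
    fit = stats.linregress(years, values)
    slope_rel = fit.slope / first
    se = fit.stderr / abs(first)
    if not np.isfinite(se):   # perfect fit (e.g. constant series)
        se = 0.0
    period = (int(years[0]), int(years[-1]))
    return RelativeTrend(slope_rel=slope_rel, se=se, period=period,
                         percent_change=slope_rel * (period[1] - period[0]) * 100.0)


def supranational_index(national: pd.DataFrame, weights: dict) -> pd.DataFrame:
    """Population-weighted geometric mean of national index series.

    ``national`` has columns (country, year, index); ``weights`` maps
    country to its national population size (> 0).  Each national series is
    rebased to the first common year, combined as exp(Σ w·log idx / Σ w),
    and the result rebased to 100.  Returns columns (year, index).
    """
    wide = national.pivot(index="year", columns="country", values="index")
    wide = wide.dropna(axis=0, how="any")
    if wide.empty:
        raise ValueError("no common year coverage across countries")
    if (wide <= 0).any().any():
        raise ValueError("national indices must be positive")
    w = np.array([weights[c] for c in wide.columns], dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    rebased = wide / wide.iloc[0]
    logmix = (np.log(rebased.to_numpy()) @ w) / w.sum()
    idx = 100.0 * np.exp(logmix)
    return pd.DataFrame({"year": wide.index.to_numpy(), "index": idx})


@dataclass
class MsiSeries:
    """Multispecies index with Monte Carlo confidence band."""

    table: pd.DataFrame   # columns: year, msi, lo, hi, n_species
    alpha: float
    n_mc: int


def msi(indices: pd.DataFrame, n_mc: int = 1000, seed: int = 0,
        alpha: float = 0.05, base_year: int | None = None) -> MsiSeries:
    """Multispecies index across species with Monte Carlo uncertainty.

    ``indices`` has columns (species, year, index, se).  The point estimate
    is the geometric mean across species of each species' series rebased to
    the base year, itself rebased to 100 at the base year.  The confidence
    band resamples each species-year index from a lognormal matched to
    (index, se), recomputes the MSI, and takes the (alpha/2, 1 − alpha/2)
    quantiles.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    wide = indices.pivot(index="year", columns="species", values="index")
    wide = wide.dropna(axis=0, how="any")
    if wide.empty:
        raise ValueError("no overlapping years across species")
    if (wide <= 0).any().any():
        raise ValueError("indices must be positive")
    se = indices.pivot(index="year", columns="species", values="se")
    se = se.reindex(index=wide.index, columns=wide.columns).fillna(0.0).to_numpy()
    vals = wide.to_numpy()
    years = wide.index.to_numpy()
    b = 0 if base_year is None else int(np.flatnonzero(years == base_year)[0])

    def _compose(v):
        # v: (n_mc?, years, species); rebase per species, geometric mean, rebase
        reb = v / v[..., b:b + 1, :]
        m = np.exp(np.log(reb).mean(axis=-1))
        return 100.0 * m / m[..., b:b + 1]

    point = _compose(vals)
    rng = np.random.default_rng(seed)
    m2, s2 = vals ** 2, se ** 2
    mu = np.log(m2 / np.sqrt(m2 + s2))
    sigma = np.sqrt(np.log1p(s2 / m2))
    draws = np.exp(mu + sigma * rng.standard_normal((n_mc,) + vals.shape))
    mc = _compose(draws)
    lo = np.quantile(mc, alpha / 2, axis=0)
    hi = np.quantile(mc, 1 - alpha / 2, axis=0)
    table = pd.DataFrame({"year": years, "msi": point,
                          "lo": np.minimum(lo, point), "hi": np.maximum(hi, point),
                          "n_species": wide.shape[1]})
    return MsiSeries(table=table, alpha=alpha, n_mc=n_mc)


def group_msi(indices: pd.DataFrame, members: dict, **kwargs) -> dict:
    """MSI per named species group (e.g. habitat guilds from a trait table)."""
    out = {}
    for name, species in members.items():
        sub = indices[indices["species"].isin(species)]
        if sub.empty:
            continue
        out[name] = msi(sub, **kwargs)
    return out
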
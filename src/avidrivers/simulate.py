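"""Seeded generators for multi-country pressure/species panels and for the
canonical coupled dynamical systems used to validate CCM and the S-map.

The panel generators emulate the structure of European breeding-bird
monitoring data: a handful of annual pressure series per country (linear
trend plus Gaussian noise, percent-cover series clipped to [0, 100]) and
per-species national abundance indices rebased to 100 in the first year.
Species dynamics follow a Ricker-type recurrence on log abundance driven by
within-country standardized pressures, so the generating effect sizes
("beta", in log-index units per standard deviation of pressure per year) are
comparable across pressures — the same scale on which the S-map stage
reports its coefficients.

One global seed expands into independent substreams (pressure noise, process
noise, observation noise, per-species streams) through
``numpy.random.SeedSequence`` spawning, so each stage is individually
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import COVER_PRESSURES, DEFAULT_PRESSURES

__all__ = [
    "EffectMatrix", "CoupledLogisticSpec", "gen_pressure_panel",
    "gen_species_panel", "gen_coupled_logistic", "gen_trait_table",
    "default_effect_matrix", "species_rng",
]

# default per-pressure generator settings: baseline centre, per-country
# baseline spread, trend slope per year (with per-country heterogeneity
# ``slope_spread``) and iid interannual noise sd.  Units: percent cover for
# the land-use pressures, degrees Celsius for temperature.  Slopes are of
# the order European national statistics show for these pressures (relative
# trends of a few tenths of a percent per year) with interannual
# variability of realistic size, so the series are trend-plus-fluctuation,
# not smooth ramps.
PRESSURE_DEFAULTS = {
    "farm_input":  dict(baseline=40.0, spread=15.0, slope=0.1,  slope_spread=0.1,  sd=1.0),
    "forest":      dict(baseline=35.0, spread=10.0, slope=0.04, slope_spread=0.04, sd=0.3),
    "urban":       dict(baseline=4.0,  spread=2.0,  slope=0.01, slope_spread=0.01, sd=0.05),
    "temperature": dict(baseline=9.0,  spread=3.0,  slope=0.05, slope_spread=0.02, sd=0.4),
}


def species_rng(seed: int, species_id: str, stream: str = "") -> np.random.Generator:
    """Generator keyed by (seed, species label[, stream name]).

    Keying by a label hash rather than positional index makes every
    per-species stream invariant to the ordering of species in the panel.
    """
    key = zlib.crc32(f"{species_id}|{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class EffectMatrix:
    """Ground-truth generating parameters for a synthetic species panel.

    ``beta`` holds the per-unit effect of each (z-scored) pressure on the
    species' log index per year.  The remaining columns are per-species
    dynamics parameters: intrinsic growth ``r``, carrying capacity ``K``
    (density dependence acts through exp(n)/K), process noise sd and
    multiplicative observation noise sd.
    """

    beta: pd.DataFrame                       # species x pressure
    r: pd.Series = None                      # intrinsic growth
    carrying_capacity: pd.Series = None
    process_sd: pd.Series = None
    obs_sd: pd.Series = None

    def __post_init__(self):
        sp = self.beta.index
        if self.r is None:
            self.r = pd.Series(0.5, index=sp)
        if self.carrying_capacity is None:
            self.carrying_capacity = pd.Series(100.0, index=sp)
        if self.process_sd is None:
            self.process_sd = pd.Series(0.05, index=sp)
        if self.obs_sd is None:
            self.obs_sd = pd.Series(0.05, index=sp)
        if not np.isfinite(self.beta.to_numpy(dtype=float)).all():
            raise ValueError("beta must be finite")
        if (self.process_sd < 0).any() or (self.obs_sd < 0).any():
            raise ValueError("noise sds must be >= 0")

    @property
    def species(self):
        return list(self.beta.index)

    @property
    def pressures(self):
        return list(self.beta.columns)


def default_effect_matrix(n_species: int, affected_fraction: float = 0.6,
                          beta: float = -0.2, pressure: str = "farm_input",
                          pressures=DEFAULT_PRESSURES) -> EffectMatrix:
    """Effect matrix with one active pressure affecting a fixed fraction.

    The first ``round(affected_fraction * n_species)`` species carry effect
    ``beta`` for ``pressure``; all other cells are zero.  Deterministic so
    that the ground truth is unambiguous in recovery experiments.
    """
    species = [f"sp{i:03d}" for i in range(n_species)]
    mat = pd.DataFrame(0.0, index=species, columns=list(pressures))
    n_aff = int(round(affected_fraction * n_species))
    mat.iloc[:n_aff, mat.columns.get_loc(pressure)] = beta
    return EffectMatrix(beta=mat)


# ---------------------------------------------------------------------------
# pressure panel
# ---------------------------------------------------------------------------

def gen_pressure_panel(n_countries: int = 28, years=range(2007, 2017),
                       settings: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a pressure panel: baseline + slope·(year − year0) + noise.

    ``settings`` maps pressure id to a dict with keys ``baseline`` (central
    level), ``spread`` (sd of the per-country baseline draw), ``slope``
    (units/year) and ``sd`` (iid Gaussian noise).  Percent-cover pressures
    are clipped to [0, 100].
    """
    years = np.asarray(list(years))
    if years.size < 4:
        raise ValueError("years span must be >= 4")
    settings = {**{k: dict(v) for k, v in PRESSURE_DEFAULTS.items()},
                **(settings or {})}
    for cfg in settings.values():
        if cfg.get("sd", 0.0) < 0:
            raise ValueError("noise sd must be >= 0")
    ss = np.random.SeedSequence([int(seed), zlib.crc32(b"pressures")])
    rng = np.random.default_rng(ss)
    countries = [f"C{i:02d}" for i in range(n_countries)]
    rows = []
    t = years - years[0]
    for c in countries:
        for pid, cfg in settings.items():
            base = cfg["baseline"] + cfg.get("spread", 0.0) * rng.standard_normal()
            slope = cfg["slope"] + cfg.get("slope_spread", 0.0) * rng.standard_normal()
            vals = base + slope * t + cfg["sd"] * rng.standard_normal(len(t))
            if pid in COVER_PRESSURES:
                vals = np.clip(vals, 0.0, 100.0)
            rows.append(pd.DataFrame({"country": c, "year": years,
                                      "pressure": pid, "value": vals}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# species panel
# ---------------------------------------------------------------------------

def _standardize_pressures(pressures: pd.DataFrame) -> pd.DataFrame:
    """Within-country z-scores of each pressure series (wide per country)."""
    z = pressures.copy()
    def _z(v):
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else v * 0.0
    z["z"] = z.groupby(["country", "pressure"])["value"].transform(_z)
    return z


def gen_species_panel(pressures: pd.DataFrame, effects: EffectMatrix,
                      seed: int = 0, base_value: float = 100.0):
    """Simulate species index panels driven by the given pressures.

    Latent log abundance per (species, country) follows

        n[t+1] = n[t] + r·(1 − exp(n[t])/K) + Σ_j beta_j·z_j[t] + ε[t]

    with ``z`` the within-country z-scored pressures and ε Gaussian process
    noise.  The observed index is exp(n) rebased to ``base_value`` at the
    first year with multiplicative lognormal observation noise; the reported
    se column is index·obs_sd.  Returns ``(panel, latent)`` where ``latent``
    holds the noise-free-observation (rebased) trajectories.
    """
    z = _standardize_pressures(pressures)
    years = np.sort(pressures["year"].unique())
    countries = sorted(pressures["country"].unique())
    pids = effects.pressures
    zw = {c: g.pivot(index="year", columns="pressure", values="z").reindex(
              index=years, columns=pids).to_numpy()
          for c, g in z.groupby("country")}
    for c, m in zw.items():
        if np.isnan(m).any():
            raise ValueError(f"pressure panel incomplete for country {c}")
    obs_rows, lat_rows = [], []
    T = len(years)
    for sp in effects.species:
        beta = effects.beta.loc[sp, pids].to_numpy(dtype=float)
        r = float(effects.r[sp]); K = float(effects.carrying_capacity[sp])
        psd = float(effects.process_sd[sp]); osd = float(effects.obs_sd[sp])
        rng_p = species_rng(seed, sp, "process")
        rng_o = species_rng(seed, sp, "observation")
        for c in countries:
            zmat = zw[c]
            n = np.empty(T)
            n[0] = np.log(K)
            eps = psd * rng_p.standard_normal(T - 1)
            for t in range(T - 1):
                n[t + 1] = (n[t] + r * (1.0 - np.exp(n[t]) / K)
                            + float(zmat[t] @ beta) + eps[t])
                if not np.isfinite(n[t + 1]) or abs(n[t + 1]) > 50:
                    raise OverflowError(
                        f"latent trajectory diverged for {sp}/{c}; "
                        "use smaller |beta| or r")
            latent = np.exp(n)
            latent_idx = base_value * latent / latent[0]
            noise = np.exp(osd * rng_o.standard_normal(T)) if osd > 0 else 1.0
            observed = latent_idx * noise
            observed = base_value * observed / observed[0]
            obs_rows.append(pd.DataFrame({
                "species": sp, "country": c, "year": years,
                "index": observed, "se": observed * osd}))
            lat_rows.append(pd.DataFrame({
                "species": sp, "country": c, "year": years, "index": latent_idx}))
    return (pd.concat(obs_rows, ignore_index=True),
            pd.concat(lat_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# coupled logistic maps
# ---------------------------------------------------------------------------

@dataclass
class CoupledLogisticSpec:
    """Two coupled logistic maps replicated over independent segments.

        x[t+1] = x[t]·(r_x − r_x·x[t] − beta_xy·y[t])
        y[t+1] = y[t]·(r_y − r_y·y[t] − beta_yx·x[t])

    ``beta_xy`` is the effect of Y on X and ``beta_yx`` the effect of X on
    Y; the unidirectional benchmark (X drives Y) uses ``beta_xy = 0``,
    ``beta_yx > 0``.  Segments play the role of countries: independent
    initial conditions, no dynamical connection between segments.
    """

    r_x: float = 3.8
    r_y: float = 3.8
    beta_xy: float = 0.0
    beta_yx: float = 0.32
    n_segments: int = 25
    m: int = 12
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.r_x <= 4 and 0 < self.r_y <= 4):
            raise ValueError("growth parameters must lie in (0, 4]")
        if self.m < 4:
            raise ValueError("m must be >= 4")


def gen_coupled_logistic(spec: CoupledLogisticSpec, max_retries: int = 50) -> pd.DataFrame:
    """Simulate the coupled maps; returns columns segment, t, x, y.

    Initial conditions are resampled (up to ``max_retries`` per segment)
    whenever a trajectory escapes (0, 1); an error is raised if none of the
    retries stays bounded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed),
                                                        zlib.crc32(b"logistic")]))
    rows = []
    total = spec.burn_in + spec.m
    for s in range(spec.n_segments):
        for _ in range(max_retries):
            x = np.empty(total); y = np.empty(total)
            x[0], y[0] = rng.uniform(0.1, 0.9, size=2)
            ok = True
            for t in range(total - 1):
                x[t + 1] = x[t] * (spec.r_x - spec.r_x * x[t] - spec.beta_xy * y[t])
                y[t + 1] = y[t] * (spec.r_y - spec.r_y * y[t] - spec.beta_yx * x[t])
                if not (0 < x[t + 1] < 1 and 0 < y[t + 1] < 1):
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"segment {s}: trajectory escaped (0, 1) after {max_retries} retries")
        rows.append(pd.DataFrame({"segment": s, "t": np.arange(spec.m),
                                  "x": x[spec.burn_in:], "y": y[spec.burn_in:]}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def gen_trait_table(species_ids, seed: int = 0,
                    habitat_probs: dict | None = None,
                    p_migrant_long: float = 0.3,
                    diet_probs: dict | None = None,
                    ssi_logmean: float = 0.0, ssi_logsd: float = 0.5,
                    sti_mean: float = 12.0, sti_sd: float = 3.0) -> pd.DataFrame:
    """Random trait table with the given class probabilities.

    Habitat flags are drawn independently per habitat; diet is a single
    categorical draw; SSI is lognormal (positive) and STI normal (°C).
    """
    habitat_probs = {**{"farmland": 0.3, "woodland": 0.35, "urban": 0.3},
                     **(habitat_probs or {})}
    diet_probs = diet_probs or {"granivorous": 0.2, "invertebrate": 0.5, "other": 0.3}
    diets = list(diet_probs)
    dp = np.array([diet_probs[d] for d in diets], dtype=float)
    dp = dp / dp.sum()
    rows = []
    for sp in species_ids:
        rng = species_rng(seed, sp, "traits")
        hab = [h for h in ("farmland", "woodland", "urban")
               if rng.random() < habitat_probs[h]]
        rows.append({
            "species": sp,
            "habitat": ";".join(hab),
            "migrant_long": bool(rng.random() < p_migrant_long),
            "diet": diets[int(rng.choice(len(diets), p=dp))],
            "ssi": float(np.exp(ssi_logmean + ssi_logsd * rng.standard_normal())),
            "sti": float(sti_mean + sti_sd * rng.standard_normal()),
        })
    cols = ["species", "habitat", "migrant_long", "diet", "ssi", "sti"]
    return pd.DataFrame(rows, columns=cols)
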
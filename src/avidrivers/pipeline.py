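"""End-to-end orchestration: trend stage, time-series stage, trait stage.

The three stages mirror the analytical design of the attribution study this
package implements:

1. **trend stage** — the relative trend of every (species, country) index
   series is regressed (PLS with bootstrap BCa intervals) on eight country
   predictors: each pressure's baseline (its temporal mean over the window)
   and its relative trend;
2. **time-series stage** — per species, per-country series are z-scored,
   an embedding dimension selected, noise-dominated series screened out,
   each pressure tested by multispatial CCM, and the significant pressures
   quantified by per-country S-maps whose temporal-mean coefficients are
   averaged across countries into a signed interaction strength;
3. **trait stage** — per pressure, the interaction strengths are regressed
   on species traits (habitat, migration, diet, SSI, STI) by PLS.

Every exclusion (too few countries, failed nonlinearity screen, no
significant pressure, infeasible S-map) carries a reason code in the run
report; nothing is dropped silently.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edm, smap
from .panels import (DEFAULT_PRESSURES, RunConfig, interpolate_pressure_panel,
                     trait_design_matrix, _write_csv)
from .pls import PlsFit, pls_with_bootstrap
from .trends import relative_trend

logger = logging.getLogger("avidrivers")


def _subseed(seed: int, *labels) -> np.random.SeedSequence:
    """Substream keyed by string labels, invariant to input ordering."""
    key = zlib.crc32("|".join(str(x) for x in labels).encode())
    return np.random.SeedSequence([int(seed), key])


# ---------------------------------------------------------------------------
# trend stage
# ---------------------------------------------------------------------------

@dataclass
class TrendStageResult:
    pls: PlsFit
    design: pd.DataFrame          # one row per (species, country)
    exclusions: list              # dicts with species/country/reason


def run_trend_stage(species: pd.DataFrame, pressures: pd.DataFrame,
                    config: RunConfig) -> TrendStageResult:
    """PLS of (species, country) relative trends on pressure predictors."""
    y0, y1 = config.trend_years
    sp = species[(species["year"] >= y0) & (species["year"] <= y1)]
    pr = pressures[(pressures["year"] >= y0) & (pressures["year"] <= y1)]
    pids = sorted(pr["pressure"].unique())
    # per-country predictors: baseline (mean) and relative trend per pressure
    preds = {}
    for (c, p), g in pr[pr["value"].notna()].groupby(["country", "pressure"]):
        row = preds.setdefault(c, {})
        row[f"{p}_baseline"] = g["value"].mean()
        if len(g) >= 3:
            try:
                row[f"{p}_trend"] = relative_trend(g["year"], g["value"]).slope_rel
            except ValueError:
                pass
    pred_df = pd.DataFrame.from_dict(preds, orient="index")
    cols = [f"{p}_{kind}" for p in pids for kind in ("baseline", "trend")]
    pred_df = pred_df.reindex(columns=cols)

    rows, exclusions = [], []
    for (s, c), g in sp[sp["index"].notna()].groupby(["species", "country"]):
        if len(g) < 3:
            exclusions.append({"species": s, "country": c,
                               "reason": "fewer than 3 years"})
            continue
        if c not in pred_df.index:
            exclusions.append({"species": s, "country": c,
                               "reason": "no pressure data"})
            continue
        tr = relative_trend(g["year"], g["index"])
        rows.append({"species": s, "country": c, "trend": tr.slope_rel,
                     "trend_se": tr.se, **pred_df.loc[c].to_dict()})
    design = pd.DataFrame(rows)
    if len(design) < 3:
        raise ValueError(f"trend stage has {len(design)} rows; >= 3 required")
    X = design[cols]
    try:
        fit = pls_with_bootstrap(X, design["trend"], n_boot=config.pls_n_boot,
                                 alpha=config.alpha, cv_folds=config.cv_folds,
                                 cv_repeats=config.cv_repeats, seed=config.seed)
    except ValueError as exc:
        if "constant" in str(exc):
            raise ValueError(f"configuration error: {exc}") from exc
        raise
    logger.info("trend stage: %d rows (%d excluded), n_comp=%d",
                len(design), len(exclusions), fit.n_comp)
    return TrendStageResult(pls=fit, design=design, exclusions=exclusions)


# ---------------------------------------------------------------------------
# time-series stage
# ---------------------------------------------------------------------------

@dataclass
class TsStageResult:
    effects: list                  # smap.PressureEffect
    counts: pd.DataFrame           # per-pressure signed counts
    species_records: pd.DataFrame  # per-species E, screen outcome, status
    no_impact: list                # species ids with no identified impact
    exclusions: list
    ccm_table: pd.DataFrame = None  # one row per (species, pressure) tested


def _complete_segments(df: pd.DataFrame, value_col: str, years: np.ndarray):
    """country -> series ndarray, for countries complete on ``years``."""
    out = {}
    for c, g in df.groupby("country"):
        g = g.set_index("year")[value_col].reindex(years)
        if g.notna().all():
            out[c] = g.to_numpy(dtype=float)
    return out


def run_ts_stage(species: pd.DataFrame, pressures: pd.DataFrame,
                 config: RunConfig) -> TsStageResult:
    """CCM screening plus S-map quantification for every species."""
    y0, y1 = config.ts_years
    years = np.arange(y0, y1 + 1)
    pr = pressures[(pressures["year"] >= y0) & (pressures["year"] <= y1)]
    pr, interpolated = interpolate_pressure_panel(pr, years)
    if interpolated:
        logger.info("interpolated pressure series: %s", interpolated)
    pids = sorted(pr["pressure"].unique())
    pressure_series = {p: _complete_segments(pr[pr["pressure"] == p], "value", years)
                       for p in pids}
    sp = species[(species["year"] >= y0) & (species["year"] <= y1)]

    effects, records, exclusions, no_impact, ccm_rows = [], [], [], [], []
    for s, g in sp.groupby("species"):
        rec = {"species": s, "status": "", "E": np.nan, "n_countries": 0}
        segs = _complete_segments(g[g["index"].notna()], "index", years)
        countries = [c for c in sorted(segs)
                     if all(c in pressure_series[p]
                            and np.std(pressure_series[p][c]) > 0 for p in pids)
                     and np.std(segs[c]) > 0]
        rec["n_countries"] = len(countries)
        if len(countries) < config.min_countries:
            rec["status"] = "excluded: too few usable countries"
            exclusions.append({"species": s, "reason": rec["status"]})
            records.append(rec)
            continue
        y_segs = edm.standardize_segments([segs[c] for c in countries])
        x_segs = {p: edm.standardize_segments(
                      [pressure_series[p][c] for c in countries]) for p in pids}
        m_min = min(len(v) for v in y_segs)
        E = edm.select_embedding_dim(y_segs, min(config.e_max, m_min - 1),
                                     config.tau)
        rec["E"] = E
        screen = edm.test_nonlinearity(
            y_segs, E, config.tau, seed=_subseed(config.seed, s, "screen"))
        rec["screen_passes"] = screen.passes
        rec["screen_reason"] = screen.reason
        if config.exclude_nonlinearity_failures and not screen.passes:
            rec["status"] = f"no identified impact (screen: {screen.reason})"
            no_impact.append(s)
            records.append(rec)
            continue
        ccm_results = {}
        for p in pids:
            ccm_results[p] = edm.ccm(
                y_segs, x_segs[p], E, n_boot=config.ccm_n_boot,
                alpha=config.alpha, seed=_subseed(config.seed, s, p),
                tau=config.tau, source=p, target=s)
        if config.bh_correction:
            _apply_bh(ccm_results, config.alpha)
        for p in pids:
            ccm_rows.append({"species": s, "n_countries": len(countries),
                             **ccm_results[p].to_dict()})
        block = smap.build_block(y_segs, x_segs, ccm_results, E, config.alpha)
        if block.skipped:
            rec["status"] = "no identified impact (no significant pressure)"
            no_impact.append(s)
            records.append(rec)
            continue
        fits = {}
        for si, c in enumerate(countries):
            if si not in block.by_segment:
                continue
            X, yb = block.by_segment[si]
            if len(X) < X.shape[1] + 2:
                continue   # S-map infeasible for this country's series length
            theta = smap.select_theta(
                X, yb, grid=config.theta_grid,
                seed=_subseed(config.seed, s, c, "theta"))
            fits[c] = smap.smap_solve(X, yb, theta, col_names=block.col_names)
        if not fits:
            rec["status"] = "no identified impact (S-map infeasible)"
            no_impact.append(s)
            records.append(rec)
            continue
        eff = smap.aggregate_effects(
            fits, s, ccm_results=ccm_results, alpha=config.alpha,
            seed=_subseed(config.seed, s, "aggregate"))
        effects.extend(eff)
        rec["status"] = "impact identified"
        rec["theta_mean"] = float(np.mean([f.theta for f in fits.values()]))
        records.append(rec)
    counts = smap.count_signed_effects(effects, pressures=pids)
    logger.info("ts stage: %d species with impact, %d without, %d excluded",
                len({e.species for e in effects}), len(no_impact), len(exclusions))
    return TsStageResult(effects=effects, counts=counts,
                         species_records=pd.DataFrame(records),
                         no_impact=no_impact, exclusions=exclusions,
                         ccm_table=pd.DataFrame(ccm_rows))


def _apply_bh(ccm_results: dict, alpha: float) -> None:
    """Benjamini–Hochberg across the pressures tested for one species."""
    items = [(p, r) for p, r in ccm_results.items() if r is not None]
    ps = np.array([r.p_value for _, r in items])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank, i in enumerate(order[::-1]):
        k = m - rank
        prev = min(prev, ps[i] * m / k)
        adj[i] = prev
    for (p, r), pa in zip(items, adj):
        r.p_value = float(pa)
        r.convergent = bool(pa < alpha and r.rho_by_L[-1] > 0)


# ---------------------------------------------------------------------------
# trait stage
# ---------------------------------------------------------------------------

def run_trait_stage(effects, traits: pd.DataFrame, config: RunConfig,
                    skip_small: bool = False) -> dict:
    """Per-pressure PLS of interaction strengths on species traits.

    Constant trait columns (a class absent from the analyzed cohort) are
    dropped with a log line rather than failing the regression.  A cohort
    with fewer than three species cannot be regressed: by default this is
    an error; with ``skip_small`` the pressure is skipped and logged (used
    by the full-pipeline runner).
    """
    eff = pd.DataFrame([{"species": e.species, "pressure": e.pressure,
                         "effect": e.effect} for e in effects])
    if eff.empty:
        return {}
    design = trait_design_matrix(traits)
    missing = sorted(set(eff["species"]) - set(design.index))
    if missing:
        raise ValueError(f"species missing from trait table: {missing}")
    out = {}
    for p, g in eff.groupby("pressure"):
        if len(g) < 3:
            if skip_small:
                logger.info("trait stage %s: only %d species with an "
                            "identified impact; skipped", p, len(g))
                continue
            raise ValueError(
                f"trait stage for {p}: n >= 3 species required, got {len(g)}")
        X = design.loc[g["species"]]
        keep = [c for c in X.columns if X[c].nunique() > 1]
        dropped = set(X.columns) - set(keep)
        if dropped:
            logger.info("trait stage %s: dropping constant columns %s",
                        p, sorted(dropped))
        if not keep:
            continue
        out[p] = pls_with_bootstrap(
            X[keep], g["effect"].to_numpy(), n_boot=config.pls_n_boot,
            alpha=config.alpha, cv_folds=min(config.cv_folds, len(g)),
            cv_repeats=config.cv_repeats,
            seed=_subseed(config.seed, p, "traits").generate_state(1)[0] % (2**31))
    return out


# ---------------------------------------------------------------------------
# robustness to data removal
# ---------------------------------------------------------------------------

def robustness_removal(species: pd.DataFrame, pressures: pd.DataFrame,
                       config: RunConfig, stage: str = "ts",
                       fraction: float = 0.1, n_repeats: int = 5,
                       seed: int = 0) -> pd.DataFrame:
    """Rerun a stage with randomly removed species observations.

    Reports, per repeat, the sign-agreement rate of the stage's effects
    (time-series stage) or PLS coefficients (trend stage) against the
    full-data run.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    if stage not in ("ts", "trend"):
        raise ValueError("stage must be 'ts' or 'trend'")

    def signs(sp):
        if stage == "ts":
            res = run_ts_stage(sp, pressures, config)
            return {(e.species, e.pressure): np.sign(e.effect)
                    for e in res.effects}
        res = run_trend_stage(sp, pressures, config)
        return dict(zip(res.pls.predictors, np.sign(res.pls.coef)))

    ref = signs(species)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        if fraction == 0:
            sub = species
        else:
            keep = rng.random(len(species)) >= fraction
            sub = species[keep]
        got = signs(sub)
        shared = set(ref) & set(got)
        agree = (np.mean([ref[k] == got[k] for k in shared])
                 if shared else np.nan)
        rows.append({"repeat": rep, "n_removed": len(species) - len(sub),
                     "n_shared": len(shared), "sign_agreement": agree})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class AttributionReport:
    trend_stage: TrendStageResult
    ts_stage: TsStageResult
    trait_stage: dict
    provenance: dict


def run_all(species: pd.DataFrame, pressures: pd.DataFrame,
            traits: pd.DataFrame, config: RunConfig,
            out_dir=None) -> AttributionReport:
    """Run all three stages and (optionally) write the summary tables."""
    trend = run_trend_stage(species, pressures, config)
    ts = run_ts_stage(species, pressures, config)
    trait = run_trait_stage(ts.effects, traits, config, skip_small=True)
    provenance = {"seed": config.seed, "config_hash": config.hash(),
                  "n_species": int(species["species"].nunique()),
                  "exclusions": {"trend": trend.exclusions,
                                 "ts": ts.exclusions,
                                 "no_impact": ts.no_impact}}
    report = AttributionReport(trend_stage=trend, ts_stage=ts,
                               trait_stage=trait, provenance=provenance)
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def write_report(report: AttributionReport, config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"seed={config.seed} config={config.hash()}"
    _write_csv(report.trend_stage.pls.to_frame(), out / "trend_pls.csv", tag)
    eff = pd.DataFrame([e.__dict__ for e in report.ts_stage.effects])
    if eff.empty:
        eff = pd.DataFrame(columns=["species", "pressure", "effect",
                                    "n_countries", "sign", "significant"])
    _write_csv(eff, out / "ts_effects.csv", tag)
    _write_csv(report.ts_stage.counts, out / "ts_signed_counts.csv", tag)
    _write_csv(report.ts_stage.species_records, out / "ts_species_records.csv", tag)
    if report.ts_stage.ccm_table is not None and len(report.ts_stage.ccm_table):
        _write_csv(report.ts_stage.ccm_table, out / "ts_ccm.csv", tag)
    for p, fit in report.trait_stage.items():
        _write_csv(fit.to_frame(), out / f"trait_pls_{p}.csv", tag)
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
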
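"""Tabular panels: readers, writers, validation and small panel utilities.

Three tables drive every analysis in this package:

* a **species abundance-index panel** — one row per (species, country, year)
  with the national abundance index (dimensionless, rebased so the base year
  equals a declared value, 100 by default) and its standard error;
* a **pressure panel** — one row per (country, year, pressure) with the
  pressure value (percent cover for land-use pressures, degrees Celsius for
  temperature);
* a **species trait table** — one row per species with habitat membership
  flags, migration class, breeding-season diet class, the habitat
  specialization index (SSI) and the species temperature index (STI).

All files are comma-separated UTF-8 with ``.`` as the decimal mark; missing
values are empty cells.  Missing index values stay explicit nulls — an
abundance index is positive by construction, so zero never encodes
"missing".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("avidrivers")

#: canonical pressure identifiers; user-defined identifiers are accepted too
DEFAULT_PRESSURES = ("farm_input", "forest", "urban", "temperature")
#: pressures expressed as percent cover, constrained to [0, 100]
COVER_PRESSURES = frozenset({"farm_input", "forest", "urban"})

HABITATS = ("farmland", "woodland", "urban")
DIETS = ("granivorous", "invertebrate", "other")

SPECIES_COLUMNS = ["species", "country", "year", "index", "se"]
PRESSURE_COLUMNS = ["country", "year", "pressure", "value"]
TRAIT_COLUMNS = ["species", "habitat", "migrant_long", "diet", "ssi", "sti"]


class PanelValidationError(ValueError):
    """Raised when a panel violates a structural invariant."""


# ---------------------------------------------------------------------------
# species index panel
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise PanelValidationError(f"{path}: unparsable CSV ({exc})") from exc


def validate_species_panel(df: pd.DataFrame, base_value: float = 100.0,
                           check_base: bool = True, tol: float = 1e-9) -> pd.DataFrame:
    """Validate a species index panel; returns the sorted panel.

    Checks: required columns, no duplicate (species, country, year) keys,
    strictly positive indices and non-negative standard errors where present,
    and (optionally) that each series' first observed index equals
    ``base_value`` within ``tol``.
    """
    missing_cols = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"species panel missing columns: {missing_cols}")
    df = df.copy()
    bad_year = df["year"].isna() | (df["year"].astype(float) % 1 != 0)
    if bad_year.any():
        row = int(np.flatnonzero(bad_year.to_numpy())[0])
        raise PanelValidationError(f"unparsable year at row {row}")
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["species", "country", "year"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate key {r['species']}/{r['country']}/{r['year']}")
    present = df["index"].notna()
    if (df.loc[present, "index"] <= 0).any():
        r = df[present & (df["index"] <= 0)].iloc[0]
        raise PanelValidationError(
            f"non-positive index for {r['species']}/{r['country']}/{r['year']}; "
            "indices must be positive")
    if (df["se"].dropna() < 0).any():
        raise PanelValidationError("negative standard error in species panel")
    df = df.sort_values(["species", "country", "year"]).reset_index(drop=True)
    if check_base:
        firsts = df[present].groupby(["species", "country"], sort=False).first()
        off = firsts[np.abs(firsts["index"] - base_value) > tol]
        if len(off):
            key = off.index[0]
            raise PanelValidationError(
                f"series {key[0]}/{key[1]} starts at {off['index'].iloc[0]}, "
                f"expected base value {base_value}; pass rebase=True to rebase")
    return df


def read_species_panel(path, base_value: float = 100.0,
                       rebase: bool = False) -> pd.DataFrame:
    """Read and validate a species abundance-index panel CSV.

    With ``rebase=True`` each (species, country) series is rescaled so its
    first observed year equals ``base_value`` (standard errors are rescaled
    by the same factor); otherwise a series whose base-year index disagrees
    with ``base_value`` is a validation error — rebasing is never silent.
    """
    df = _read_csv(path)
    df = validate_species_panel(df, base_value, check_base=False)
    if rebase:
        df = rebase_species_panel(df, base_value)
    return validate_species_panel(df, base_value, check_base=True)


def rebase_species_panel(df: pd.DataFrame, base_value: float = 100.0) -> pd.DataFrame:
    df = df.copy()
    first = (df.groupby(["species", "country"], sort=False)["index"]
               .transform(lambda v: v.dropna().iloc[0]))
    factor = base_value / first
    df["index"] = df["index"] * factor
    df["se"] = df["se"] * factor
    return df.reset_index(drop=True)


def write_species_panel(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_csv(df[SPECIES_COLUMNS], path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# pressure panel
# ---------------------------------------------------------------------------

def validate_pressure_panel(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PRESSURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"pressure panel missing columns: {missing_cols}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["country", "year", "pressure"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate key {r['country']}/{r['year']}/{r['pressure']}")
    cover = df["pressure"].isin(COVER_PRESSURES) & df["value"].notna()
    out = cover & ((df["value"] < 0) | (df["value"] > 100))
    if out.any():
        r = df[out].iloc[0]
        raise PanelValidationError(
            f"cover pressure {r['pressure']} out of [0, 100] "
            f"({r['value']}) for {r['country']}/{r['year']}")
    counts = df[df["value"].notna()].groupby(["country", "pressure"]).size()
    short = counts[counts < 2]
    if len(short):
        c, p = short.index[0]
        raise PanelValidationError(
            f"pressure series {c}/{p} has {short.iloc[0]} year(s); >= 2 required")
    return df.sort_values(["country", "pressure", "year"]).reset_index(drop=True)


def read_pressure_panel(path) -> pd.DataFrame:
    """Read and validate a pressure panel CSV (country, year, pressure, value)."""
    return validate_pressure_panel(_read_csv(path))


def write_pressure_panel(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_csv(df[PRESSURE_COLUMNS], path, header_comment)


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def parse_habitat(value) -> frozenset:
    """Parse a ';'-joined habitat subset ('farmland;urban', possibly empty)."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    items = frozenset(s.strip() for s in str(value).split(";") if s.strip())
    bad = items - set(HABITATS)
    if bad:
        raise PanelValidationError(f"unknown habitat(s) {sorted(bad)}")
    return items


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"trait table missing columns: {missing_cols}")
    df = df.copy()
    dup = df.duplicated(subset=["species"], keep=False)
    if dup.any():
        raise PanelValidationError(
            f"duplicate species in trait table: {df.loc[dup, 'species'].iloc[0]}")
    offenders = []
    for _, r in df.iterrows():
        try:
            parse_habitat(r["habitat"])
        except PanelValidationError:
            offenders.append(r["species"])
        if r["diet"] not in DIETS:
            offenders.append(r["species"])
    if offenders:
        raise PanelValidationError(
            f"invalid trait categories for species: {sorted(set(offenders))}")
    if (df["ssi"] <= 0).any():
        raise PanelValidationError("ssi must be positive for all species")
    df["migrant_long"] = df["migrant_long"].astype(bool)
    return df.sort_values("species").reset_index(drop=True)


def read_trait_table(path) -> pd.DataFrame:
    return validate_trait_table(_read_csv(path))


def write_trait_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_csv(df[TRAIT_COLUMNS], path, header_comment)


def trait_design_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Expand the trait table into a numeric design matrix (one row/species).

    Habitat membership and diet classes become 0/1 indicators; SSI and STI
    stay continuous.  The 'other' diet class is the omitted reference level.
    """
    rows = {}
    for _, r in traits.iterrows():
        hab = parse_habitat(r["habitat"])
        rows[r["species"]] = {
            "habitat_farmland": float("farmland" in hab),
            "habitat_woodland": float("woodland" in hab),
            "habitat_urban": float("urban" in hab),
            "migrant_long": float(bool(r["migrant_long"])),
            "diet_granivorous": float(r["diet"] == "granivorous"),
            "diet_invertebrate": float(r["diet"] == "invertebrate"),
            "ssi": float(r["ssi"]),
            "sti": float(r["sti"]),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")


# ---------------------------------------------------------------------------
# panel utilities
# ---------------------------------------------------------------------------

def interpolate_annual(years, values, request_years=None):
    """Linearly interpolate an annual series onto its full integer year range.

    Observed years pass through unchanged; interior years are interpolated
    between the bracketing observations.  No extrapolation: requesting a year
    outside the observed span is an error.  Returns ``(years, values)``
    arrays.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    years, values = years[keep], values[keep]
    if len(years) < 2:
        raise PanelValidationError("interpolation needs >= 2 observed years")
    order = np.argsort(years)
    years, values = years[order], values[order]
    lo, hi = int(years[0]), int(years[-1])
    if request_years is None:
        request_years = np.arange(lo, hi + 1)
    else:
        request_years = np.asarray(request_years)
        if request_years.min() < lo or request_years.max() > hi:
            raise PanelValidationError(
                f"requested years outside observed range [{lo}, {hi}]")
    return request_years, np.interp(request_years, years, values)


def interpolate_pressure_panel(df: pd.DataFrame, years=None):
    """Interpolate every (country, pressure) series onto annual steps.

    Returns ``(panel, interpolated_keys)`` where the second element lists the
    (country, pressure) pairs that actually required interpolation — the run
    report records which series were gap-filled.
    """
    out, filled = [], []
    for (c, p), g in df.groupby(["country", "pressure"], sort=False):
        g = g[g["value"].notna()]
        span = years
        if span is not None:
            span = [y for y in years if g["year"].min() <= y <= g["year"].max()]
        ys, vs = interpolate_annual(g["year"], g["value"], span)
        if len(ys) > g["year"].nunique():
            filled.append((c, p))
        out.append(pd.DataFrame({"country": c, "year": ys.astype(int),
                                 "pressure": p, "value": vs}))
    panel = pd.concat(out, ignore_index=True)
    return panel.sort_values(["country", "pressure", "year"]).reset_index(drop=True), filled


def august_june_mean(monthly: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a monthly series to the August(previous year)–June window.

    Input columns: year, month, value.  The window for monitoring year *y*
    spans August of *y − 1* through June of *y*, covering both the
    non-breeding and breeding seasons.  Optional helper — the pressure panel
    is normally supplied already annual.
    """
    m = monthly.copy()
    m["window_year"] = np.where(m["month"] >= 8, m["year"] + 1, m["year"])
    m = m[(m["month"] >= 8) | (m["month"] <= 6)]
    g = m.groupby("window_year").agg(value=("value", "mean"),
                                     n_months=("month", "size")).reset_index()
    g = g[g["n_months"] == 11]
    return g.rename(columns={"window_year": "year"})[["year", "value"]]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for a full pipeline run; serializable to YAML/JSON."""

    seed: int = 1
    base_year_value: float = 100.0
    alpha: float = 0.05
    # PLS / bootstrap
    pls_n_boot: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 10
    # CCM / S-map
    ccm_n_boot: int = 100
    # E <= 4 keeps the per-country S-map feasible on 10-step windows
    # (E + 2 rows needed out of m - 1 transitions, some lost to lag filling)
    e_max: int = 4
    tau: int = 1
    theta_grid: tuple = (0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
    # the screen outcome is always recorded per species; hard exclusion is
    # off by default because the decay slope is noise-dominated on short
    # annual segments (see docs/methods.md)
    exclude_nonlinearity_failures: bool = False
    min_countries: int = 3
    # MSI
    msi_n_mc: int = 1000
    # analysis windows
    trend_years: tuple = (1996, 2016)
    ts_years: tuple = (2007, 2016)
    # multiple testing across pressures (off: one test per pressure at alpha)
    bh_correction: bool = False
    out_dir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("pls_n_boot", "ccm_n_boot", "msi_n_mc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(t < 0 or t > 10 for t in self.theta_grid):
            raise ValueError("theta grid must lie within [0, 10]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def setup_logging(seed: int, level=logging.INFO) -> None:
    """Structured log lines timestamped and tagged with the run seed."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        f"%(asctime)s seed={seed} %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
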
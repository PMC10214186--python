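# avidrivers

Attribution of anthropogenic-pressure effects on bird population time
series: trend-level partial least squares with bootstrap BCa intervals,
time-series-level multispatial convergent cross mapping (CCM) with
multivariate S-map quantification, multispecies index aggregation, and a
trait-syndrome stage — for researchers working with national
abundance-index panels (annual species indices per country, rebased to
100) and country-level pressure series such as high-input farm cover,
forest cover, urbanization and temperature.

## The methods in brief

**Trends.** The relative trend of an annual series is the OLS slope scaled
by the first value, Δ = b/y₀ (fraction of the initial level per year). A
multispecies index (MSI) is the geometric mean across species of rebased
indices, with Monte Carlo confidence bands from lognormal resampling of
each (index, SE) pair.

**Trend attribution.** Per (species, country), the index trend is
regressed on eight predictors — each pressure's baseline (window mean) and
relative trend — by PLS1 (NIPALS, tolerant of missing cells), with the
component count chosen by repeated cross-validation and coefficients given
bias-corrected and accelerated (BCa) bootstrap intervals.

**Quasi-causal attribution.** Short national series are pooled into
segment-aware embeddings (lagged vectors never cross a country boundary;
E ≤ m − 1). CCM asks whether pressure X leaves a signature in species Y:
the Y-manifold cross-estimates X, and the skill ρ must be positive and
grow significantly from the smallest to the largest state library. For
species with convergent pressures, S-maps — locally weighted linear
models, weights w_k = exp(−θ‖x(t_k) − x(t*)‖/d̄), solved by SVD — yield
time-varying coefficients whose temporal and cross-country average is the
signed interaction strength of each pressure on each species (in sd/sd
units). A final PLS relates these strengths to species traits.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Generate a synthetic panel with known ground truth (40 species in 28
countries, 2007–2016; 60% of species carry a true negative effect of
high-input farm cover, β = −0.2 per pressure sd) and run the full
time-series stage:

```bash
avidrivers simulate --seed 1 --n-countries 28 --n-species 40 --out-dir synth
avidrivers smap synth/species.csv synth/pressures.csv --seed 1 --out-dir results
```

which prints

```
... seed=1 avidrivers INFO ts stage: 23 species with impact, 17 without, 0 excluded
24 effects; wrote tables to results
```

and writes `results/ts_signed_counts.csv`:

```
# seed=1 config=a97340864864
pressure,n_negative,n_positive,n_total
farm_input,23,0,23
forest,1,0,1
temperature,0,0,0
urban,0,0,0
```

Reading: of the 24 species that truly respond to farm input, 23 were
identified and every recovered mean S-map coefficient has the planted
negative sign; one species additionally picked up a spurious forest
effect (four pressures tested per species at α = 0.05), and the 16
zero-effect species all ended in the "no identified impact" set.
`results/ts_effects.csv` holds the per-species interaction strengths with
their significance flags.

The same panels feed the other subcommands: `trends` (per-series relative
trends), `msi` (multispecies indices per habitat group), `pls` (trend-stage
attribution), `traits` (trait syndromes), `run-all` (all stages plus a
JSON provenance summary), and `robustness` (sign stability under random
data removal).

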
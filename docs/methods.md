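# Methods

`avidrivers` attributes changes in bird population indices to anthropogenic
pressures with two complementary strategies: a *trend* analysis (one number
per series, related to pressure predictors by partial least squares) and a
*time-series* analysis (the full annual trajectories, related by empirical
dynamic modeling: convergent cross mapping to detect influences, S-maps to
quantify them). A third stage relates the quantified influences to species
traits. This note documents the models, the defaults and the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Data model

Inputs are three tidy CSV tables: a species abundance-index panel
(`species, country, year, index, se`; index rebased to 100 in the base
year, positive by construction, missing values as empty cells — never
zeros), a pressure panel (`country, year, pressure, value`; percent cover
in [0, 100] for `farm_input`, `forest`, `urban`, degrees Celsius for
`temperature`), and a per-species trait table (habitat subset of
{farmland, woodland, urban}, long-distance-migrant flag, diet class, SSI
specialization index > 0, STI thermal index in °C).

Urbanization-style sparse series are linearly interpolated onto annual
steps (interior years only; extrapolation is an error), and the run report
lists every series that was gap-filled. A helper aggregates monthly
temperature to the August(y−1)–June(y) window covering the non-breeding and
breeding seasons; the pressure table is normally supplied already annual.

## Trends and multispecies indices

The *relative trend* of any annual series is the OLS slope of value on year
divided by the first observed value (units: fraction of the initial level
per year); its standard error is the OLS slope standard error under the
same scaling. The percent change over a window is slope × span × 100. Both
an SE and an α-level confidence interval are always reported, since a bare
"±" is ambiguous.

Supranational species indices combine national series by a geometric mean
weighted with national population sizes. The multispecies index (MSI) is
the plain geometric mean across species of rebased indices, rebased to 100
at the base year. Uncertainty comes from Monte Carlo resampling: each
species-year index is redrawn from a lognormal whose mean and standard
deviation match the reported index and SE, the MSI recomputed, and the
(α/2, 1−α/2) quantiles taken (default 1000 draws). This is deliberately a
geometric-mean index with parametric Monte Carlo, not a state-space
smoother: it keeps the quantity fully specified by this package at the cost
of ignoring serial correlation in the index errors, so MSI bands here are
slightly anti-conservative for strongly autocorrelated index errors.

## Partial least squares with bootstrap BCa intervals

PLS1 is implemented by NIPALS with available-case inner products: every
inner product skips missing predictor cells and deflation touches observed
cells only, so predictor tables with missing values need no imputation.
Coefficients are reported on the standardized scale (sd of response per sd
of predictor). With complete data and as many components as the predictor
rank, the coefficients equal ordinary least squares on standardized data;
at high missingness the available-case scores become noisy and
coefficients attenuate toward zero — a known property of this treatment,
acceptable at the few-percent missingness the pipeline encounters.

The number of components is selected by repeated K-fold cross-validation
(default 5-fold × 10 repeats) with a one-standard-error rule toward fewer
components. The SE of the CV error uses the fold-level spread divided by
√K only: repeated splits reuse the same rows and are not independent, and
treating them as such systematically over-selected components.

Confidence intervals come from case resampling (rows of the design — one
(species, country) record each — are the resampling unit; this is a
convention of this package and is documented as such) with
bias-corrected and accelerated (BCa) endpoints: the bias correction z₀ is
the normal quantile of the fraction of bootstrap values below the point
estimate, the acceleration the jackknife skewness. When the bootstrap
distribution falls entirely on one side of the point estimate, z₀ is
infinite and that coordinate falls back to the percentile interval with a
logged warning. Component count is selected once on the full data and held
fixed across bootstrap replicates; re-running CV inside every replicate
would multiply the cost by the replicate count while changing the
coefficient distribution only through occasional count flips, and holding
the tuning fixed is the standard practice for coefficient bootstraps. A
predictor is "significant" exactly when its interval excludes zero.
Defaults: B = 1000, α = 0.05.

## State-space reconstruction on short replicated series

National series are too short (≈10 annual steps) for classical embedding,
so lagged coordinate vectors are pooled across countries: vectors are
built within a country's series only — never across a boundary — and the
pooled cloud approximates the common attractor. With m the minimum segment
length, E ≤ m − 1 (one step must remain for prediction); a segment of
length m contributes m − (E−1)τ vectors. All series are z-scored per
country first, which is what makes cross-country pooling meaningful. The
lag τ is fixed at 1 (annual data).

Simplex projection predicts a vector's future from its E + 1 nearest
neighbors with weights exp(−d/d₁) (d₁ the nearest distance; exact-distance
ties share uniform weight, and remaining ties break by vector build order
for determinism). Neighbors within τ steps of the target in the same
segment are excluded. The embedding dimension is the E ≤ E_max maximizing
leave-one-out one-step skill, ties toward smaller E. E_max defaults to 4:
for a 10-year window the downstream per-country S-map needs E + 2 rows out
of the m − 1 = 9 usable transitions, with up to E − 2 rows lost to
lag-filled columns, which is feasible only for E ≤ 4.

The nonlinearity screen asks whether a series behaves like a deterministic
dynamical system: one-step skill significantly positive (bootstrap over
prediction pairs) and skill decaying with forecast horizon (negative slope
*and* a total drop > 1e-4 — a noise-free periodic signal "decays" only at
float precision and is flagged `no decay`). The screen outcome is recorded
per species but is **not** a hard filter by default: on 10-step annual
segments the decay slope is estimated from at most four skill values whose
far-horizon entries rest on very few vectors, and using it as a gate
rejected most genuinely pressure-driven synthetic species while the CCM
convergence test already supplied the specificity (null species end in "no
identified impact" at ≈1.0 rate either way). Hard exclusion remains one
config switch away (`exclude_nonlinearity_failures`).

## Convergent cross mapping

To test whether pressure X influences species Y, the manifold of Y
cross-estimates the values of X: each Y-state's E + 1 nearest neighbors
among a random library of states carry the X values at their times, and
the skill ρ is the Pearson correlation of cross-estimates with truth. A
genuine influence leaves a signature in Y, so ρ must be positive and must
*converge* — improve as the library grows.

Two conventions matter and are fixed once:

* **Time alignment.** The Y-state at year t estimates X(t − 1). Annual
  indices respond to the previous year's pressure (count in spring year t
  reflects pressures up to t − 1), so the state carries a full signature
  of X(t − 1) but only an autocorrelation-mediated signature of X(t). With
  concurrent alignment the convergence test has almost no power on
  trend-plus-noise drivers, because what little is predictable of X(t) (its
  trend) is already predictable from tiny libraries. This is a single fixed
  convention, not a lag scan.
* **Significance.** For each library size L (default: four sizes from
  E + 2 to all vectors), 100 bootstrap libraries of L vectors are drawn
  with replacement (the target's own vector is excluded from its
  neighbors). The p-value is the bootstrap probability that skill at the
  largest library does not exceed skill at the smallest;
  `convergent` requires p < α and positive mean skill at L_max.

Calibration and power, measured by the acceptance suite on unidirectionally
coupled logistic maps (r = 3.8, coupling 0.32, 25 segments × 12 steps) and
independent-noise pairs of the same geometry: true-direction detection
≈100%, reverse-direction ≈4–8%, independent-noise false positives ≈2–5% at
α = 0.05.

## S-map interaction strengths

For the species with at least one convergent pressure, a multivariate
block is assembled: the species series first, then the significant
pressures ordered by ascending CCM p-value (ties by descending ρ(L_max)),
truncated to E − 1 pressures; missing slots are filled with lagged copies
of the species series. Per country, for every target time t* a linear
model predicting the species one year ahead is fitted to all block rows
with weights w_k = exp(−θ‖x(t_k) − x(t*)‖/d̄), d̄ the mean distance from
x(t*) to the other states; the weighted system is solved by SVD-based
least squares with a relative singular-value cutoff of 1e-8. At θ = 0
every local model equals the global OLS fit; the reported forecast skill
is a separate leave-one-out pass (the target row's weight set to zero).

θ is selected per (species, country) on a fixed grid
{0, 0.1, 0.3, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 10} by leave-one-out skill
with a plateau rule: among values within one bootstrap SD of the best
skill, the smallest wins — preferring the most global model guards against
overweighting the states closest to each target.

Because every column is z-scored per country, the time-averaged
coefficients are in sd-per-sd units ("scaled" coefficients) and comparable
across pressures. The per-(species, pressure) effect is the mean over
countries of the temporal mean coefficient; with ≥ 3 countries its
significance is a bootstrap percentile CI over countries, otherwise it is
inherited from the CCM significance. Countries whose block has fewer than
E + 2 rows are skipped and reported, never silently dropped. The signed
counts table tallies, per pressure, species with negative vs positive mean
effects among those with an identified impact.

## Pipeline

* **Trend stage** (default window 1996–2016): one row per (species,
  country) with the index relative trend as response; eight predictors per
  country — each pressure's temporal mean over the window ("baseline") and
  its relative trend. Fitted by PLS with bootstrap BCa intervals. A
  pressure panel with no temporal variation is reported as a configuration
  error.
* **Time-series stage** (default window 2007–2016): per species — z-score
  per country, select E, record the nonlinearity screen, CCM against each
  pressure, assemble the block, fit per-country S-maps at the selected θ,
  aggregate. Species with fewer than `min_countries` (default 3) usable
  countries are excluded with a reason; species with no convergent
  pressure, or no feasible country, enter the "no identified impact" set.
  No multiplicity correction is applied across the four pressures by
  default (each is tested at α); Benjamini–Hochberg across pressures per
  species is available as a config switch.
* **Trait stage**: per pressure, the species effects are regressed by PLS
  on habitat indicators, the long-distance-migrant indicator, diet
  indicators, SSI and STI. Trait indicators constant within the analyzed
  cohort are dropped with a log line; cohorts under three species are an
  error (or skipped with a log line inside the full-pipeline runner).
* **Robustness utility**: re-runs a stage with a fraction of species
  observations removed at random and reports the sign-agreement rate of
  effects (or trend-stage coefficients) against the full-data run.

Every per-species random stream is keyed by the run seed mixed with a hash
of the species label, so results are invariant to the order in which rows
arrive and reruns with the same seed are bit-identical.

## Synthetic data

The generators produce panels with the geometry of the European monitoring
data (defaults: 28 countries × 10 years for the time-series stage, 14 × 21
for the trend stage, configurable species counts) and known ground truth.

* **Pressures**: per (country, pressure), baseline + slope·(year − year₀)
  + iid Gaussian noise, cover series clipped to [0, 100]. Default
  baselines/slopes/noise are of the magnitude the European national series
  show — relative trends of a few tenths of a percent per year with
  interannual noise of comparable or larger size (farm input 40 ± 15
  baseline, 0.1 %/yr slope, 1.0 noise sd; forest 35 ± 10, 0.04, 0.3; urban
  4 ± 2, 0.01, 0.05; temperature 9 ± 3 °C, 0.05 °C/yr, 0.4) — plus
  per-country slope heterogeneity, so series are trend-plus-fluctuation,
  not smooth ramps.
* **Species**: latent log abundance follows a Ricker-type recurrence
  n_{t+1} = n_t + r(1 − eⁿ/K) + Σ_j β_j z_{j,t} + ε, with z the
  within-country z-scored pressures, so β is in log-index units per
  pressure sd per year — the same scale the S-map reports. Defaults:
  r = 0.5, K = 100, process sd 0.05, observation sd 0.05 (multiplicative
  lognormal; the reported SE column is index × sd), β = −0.2 on the
  affected 60% of species for the active pressure. The Ricker form is a
  modeling choice — real population dynamics are unknown — and the
  recurrence responding to z rather than raw pressure units is what makes
  effect sizes comparable across pressures.
* **Coupled logistic maps** (CCM/S-map benchmark): the standard pair
  x_{t+1} = x_t(r_x − r_x x_t − β_xy y_t), y analogous; segments are
  independent initial conditions, burn-in discarded, trajectories leaving
  (0, 1) re-drawn.

What the benchmarks show: that the stack detects and signs a planted
influence under realistic panel geometry and noise, with calibrated false
positives. What they do not show: robustness to observation error
structures unlike lognormal, to strongly nonstationary pressure variance,
to inter-species interactions (species are generated independently), or to
the site-count index-estimation models that produce real national indices —
all of which sit upstream of this package's inputs.

## Benchmark problem sizes

The validation suite uses 50 coupled-logistic replicates per direction and
100 independent-noise pairs for CCM calibration; a 301-step 2-D linear
stochastic system (spectral radius ≈ 0.7) for Jacobian recovery; the
n = 141, 8-predictor trend-stage fixture for PLS power (signal detection
over 20 runs; the nuisance false-positive rate pooled over 500 runs — its
true value is near its bound, so a small-sample estimate would be
dominated by Monte Carlo noise); 500 simulations × 2000 resamples for BCa
coverage; and one 28-country × 10-year × 40-species panel for end-to-end
recovery. The acceptance script recomputes the same quantities at
moderately reduced replicate counts (30/60 CCM replicates, 100 PLS runs,
300 coverage simulations), sizes chosen to keep a full from-scratch rerun
comfortable on a single CPU.

A calibration note on the PLS significance flags: case-bootstrap BCa
intervals for PLS coefficients are mildly anti-conservative at these
sample sizes — the per-predictor false-positive rate on null predictors is
≈9% at nominal α = 0.05, matching what scipy's independent BCa
implementation produces on the same statistic. Plain-correlation BCa
intervals from the same routine are calibrated (≈5%), so this is a
property of the normalized PLS statistic, not of the bootstrap code;
readers should treat borderline significance flags accordingly.
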
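# Methods

## Survey data model

A stationary visual census records every individual of the target species
within a fixed radius around a point: juveniles (total length ≤ 10 cm; the
10 cm boundary belongs to the juvenile class, configurable) within r = 2 m
and adults (> 10 cm) within r = 4 m. Density per census is
`count / (π r²)`; the default reporting unit is individuals per census
(the unit field programmes print), with per-m² available by flag.
`printed_area` reproduces the protocol-table convention of computing the
sampled area with π ≈ 3.14 before rounding (12.6 m² and 50.2 m²);
`census_area` is exact. Juvenile and adult censuses at a station are kept
as separate records sharing site, observer and year, since the nesting of
the two radii within a station is a field-protocol detail the data model
does not need.

Tables are exchanged as plain CSV (comma separator, `.` decimal, mandatory
header): `surveys.csv` with one row per (census, life stage) and
`sites.csv` with per-site benthic covers, environment and planar
coordinates in km. Unknown columns round-trip untouched. Counts must be
integers; schema violations raise errors naming the column or row.

## Permutation tests

Location differences in density use a one-way permutation ANOVA: the
observed F statistic is compared with F under uniformly random relabelling
of observations (sampled permutations, default 5000 iterations), with the
add-one estimator `p = (1 + #{F* ≥ F}) / (iter + 1)` so p is never 0 and
never below `1/(iter+1)`. Label permutation is exact under exchangeability
for the one-factor design. Degenerate inputs are defined explicitly:
all-identical values give F = 0 and p = 1; zero within-group variance with
non-zero between-group variance gives F = ∞, which the permutation
distribution handles by counting ties at infinity.

Pairwise contrasts are two-sample permutation tests on the absolute
difference of means, adjusted by Holm by default (Benjamini–Hochberg and
unadjusted available). The compact letter display letters the maximal
cliques of the "not significantly different" graph (adjusted p > α),
ordering cliques by descending group mean. Note the granularity
constraint: with 4 observations per group the two-sample permutation p
cannot fall below 2/70 ≈ 0.029, so no Holm-adjusted separation at α = 0.05
is possible over three pairs; separations at that sample size are only
visible unadjusted.

## Hurdle spatio-temporal model

Juvenile densities are zero-inflated, so occurrence and abundance are
separated (delta/hurdle model):

1. presence/absence per census: Bernoulli, logit link;
2. strictly positive density: Gamma, log link on the mean, fitted to
   non-zero censuses only.

Both stages share the linear-predictor structure — standardized covariates,
year factor (first year reference), observer random effect, spatial field —
with independent parameters per stage. Fixed effects have N(0, 100)
priors. Continuous covariates are centred/scaled by training-set
statistics; 0/1 covariates are left raw; interactions are products of
transformed columns.

The spatial field is a full-rank Matérn(ν = 1) Gaussian process on planar
site coordinates, `C(d) = σ_w² (κd) K₁(κd)` with `κ = √8 / range`, so
`range` is the practical range (correlation ≈ 0.14). With ≤ ~100 sites the
dense Cholesky is cheap and no sparse approximation is needed. The field
is static and shared across years; temporal structure enters only through
the year factor. Hyperpriors (the survey literature rarely states them):
half-Normal(0, 2²) for the observer and field standard deviations,
log-Normal(log 20 km, 1²) for the range, Gamma(2, rate 0.5) for the
Gamma-stage shape; all configurable via `Hyperpriors`.

Stage 2 models the per-census density (count/area) as continuous,
accepting the discreteness-induced misspecification inherent in counts;
the generator's continuous mode (below) provides an exactly well-specified
setting for recovery tests.

### Inference

A seeded adaptive Metropolis-within-Gibbs sampler:

- fixed effects: joint adaptive random-walk Metropolis (Haario-style
  empirical-covariance proposal, 2.38²/d scaling, Robbins–Monro step-size
  tuning frozen at the end of warmup);
- observer effects: vectorised per-level Metropolis (levels partition the
  observations, so the accept/reject decisions are independent), with a
  shared tuned step size; the observer SD updates on the log scale;
- spatial field: preconditioned Crank–Nicolson proposals under the current
  field prior, so acceptance involves only the likelihood; (σ_w, range)
  update jointly by adaptive Metropolis with a fresh Cholesky per
  proposal;
- Gamma shape: scalar adaptive Metropolis on the log scale.

Defaults: 1000 warmup iterations, 800 kept draws at thinning 2. Posterior
summaries are mean, SD and the central 95% interval; per-observation
log-likelihood draws are retained for WAIC/CPO. Runs are bit-reproducible
given a seed, and records are put into a canonical sort order before
fitting so posterior summaries do not depend on input row order.

### Prediction

Per grid cell, the posterior-mean presence probability p̂ and conditional
density μ̂ are combined as the delta expectation `p̂ · μ̂` (≤ μ̂ always,
equal iff p̂ = 1); both components are also reported. The field is
interpolated to cells by its conditional (kriging) mean, applied to each
posterior field draw under the posterior-mean hyperparameters — an
approximation that avoids a Cholesky per draw and is accurate when the
hyperparameter posterior is concentrated relative to the field posterior.
Observer effects are zero-mean nuisances and enter predictions at their
prior mean. Per-year layers apply that year's factor level; the
period-mean layer pairs time-averaged covariates with the average of the
year effects. Cells missing a covariate are flagged, never imputed.
Hotspots are cells at or above the q-quantile (default 0.9) of expected
density, ties kept.

## Model evaluation

- `WAIC = −2 Σᵢ [log meanₛ exp(llₛᵢ) − varₛ(llₛᵢ)]`, log-sum-exp
  stabilised; `p_waic = Σ varₛ`.
- `CPOᵢ = [meanₛ exp(−llₛᵢ)]⁻¹` (harmonic-mean identity), summarised as
  `LCPO = −meanᵢ log CPOᵢ`; "low CPO" in the model-choice rule refers to
  this smaller-is-better summary.
- Prediction metrics: RMSE, Pearson r, R² = r² (an n/parameter-adjusted R²
  is not reproducible without a reference definition; the squared
  correlation of posterior-mean predictions with observations is used),
  and AVEerror implemented as mean absolute error (the name follows the
  validation literature; the estimator is swappable).

Variable selection is backward elimination from the full main-effects
specification: at each step the predictor whose 95% intervals most widely
cover zero in *both* stages (smallest max |mean|/SD) is dropped, stopping
when every remaining predictor is relevant in at least one stage. Visited
specifications are ranked by WAIC (ascending), RMSE (ascending) and R²
(descending); the minimal rank sum wins, ties broken by fewer terms, then
lower WAIC. If no visited spec has all predictors relevant, the best
rank-sum spec is returned with an explicit warning flag. A full
interaction search over 12 covariates is combinatorially infeasible;
pairwise interactions can be supplied explicitly as `a:b` terms among
predictors surviving a main-effects screen.

Cross-validation: the stated protocol ("tenfold using a random half")
conflates k-fold and split-half designs; it is implemented as 10 repeated
seeded 50/50 splits — fit on one half, predict expected density on the
other — reporting Pearson r and AVEerror per repeat and pooled. Degenerate
training halves are redrawn with bounded retries.

## Abundance trend models

Yearly counts per location (or pooled region) follow
`y_t ~ Poisson(exp(μ + u_t))` with three latent processes: stationary AR1
(`u_t = ρ u_{t−1} + ε_t`), RW1 (`Δu_t ~ N(0, τ⁻¹)`) and RW2
(`Δ²u_t ~ N(0, τ⁻¹)`, favouring locally linear trends). The intrinsic
RW priors are handled by eigen-decomposing the structure matrix and
keeping only its row space — which enforces the sum-to-zero constraint
that separates `u` from `μ` — plus, for RW2, an explicit slope with a
vague N(0, 100) prior standing in for the flat null-space direction.
Missing survey years are latent states without observation terms. No
effort offset is applied by default (the trend target is raw aggregated
abundance); effort is carried in the series for reporting.

Priors: `μ ~ N(0, 100)`; `τ ~ Gamma(1, 0.01)`; AR1 correlation via
`logit((ρ+1)/2) ~ N(0, 1)`.

Sampling interweaves a non-centred adaptive Metropolis step over
(μ, hyperparameters, whitened innovations), a pCN refresh of the whitened
innovations, and centred conjugate updates given the latent path — a
Gibbs draw of τ from its Gamma conditional and a scalar Metropolis step
for ρ — after which the whitened coordinates are refreshed. The centred
updates are essential: without them the chain enters the classic funnel
(latent path pinned at zero, precision diverging). The latent path is
initialised at the interpolated observed log counts for the same reason.
Defaults: 4000 warmup, 1200 draws at thinning 3.

Model choice follows "best and most parsimonious": models are ranked by
WAIC and LCPO (minimal rank sum); models within the canonical ΔIC ≤ 2
equivalent-support band of the winner (LCPO band scaled per observation)
are treated as statistically indistinguishable, and the one with fewest
process hyperparameters (RW1 = 1 < AR1 = RW2 = 2) wins among them. With
~20 yearly observations AR1 and RW1 frequently fit within 1–3 WAIC units
of each other even when one of them generated the data, so the parsimony
band, not the raw ranking, is what makes selection stable.

Series guards: a series whose total count is below `min_total = 10` is
excluded (a handful of individuals cannot support a trend); specific years
can be dropped (e.g. years with too few censuses). Both are explicit
configuration, reported with reasons.

Trend direction between two years is the posterior probability that the
latent log mean declined; ≥ 0.9 is "declining", ≤ 0.1 "increasing"
(configurable thresholds).

## Synthetic-data generator

The generator emulates the survey programme the models assume: 6 named
locations (ITAC, TIMB, PPAR, SEBG, ARCH, PABR) under no-take /
multiple-use regimes, 28 sites by default, years 2003–2008 with the two
offshore locations starting 2005, 4 observers, and 26 censuses per
site-year (~3900 stations per life stage, the scale of the real
programme). Site covariates use a logistic-normal construction for the 7
benthic covers (softmax over covers plus a bare-substrate remainder, so
covers always sum to ≤ 1), location-centred SST/SSS (plausible ranges
24–28 °C, 36–38 PSU), log-normal depth, Bernoulli rugosity and distance
to land derived from the cross-shore coordinate. Presence and density
follow exactly the hurdle structure, with separate coefficient sets for
juveniles and adults, a shared declining year effect, observer effects
(SD 0.3) and Matérn fields (SD 0.8, range 15 km) per stage.

Two response modes: `count` draws counts from a shifted Poisson
(`1 + Poisson(max(μ·area − 1, 0))` given presence); `continuous` draws the
exact Gamma density, stores it in a `density` column, and sets the count
to its ceiling on the count scale (kept ≥ 1 so presence stays consistent —
a documented distortion of count-derived densities). Model-fitting code
prefers a `density` column when present, which makes continuous-mode
recovery tests exactly well-specified. Every generator is a pure function
of (config, seed); RNG streams are keyed by (seed, purpose tag) so
covariate and survey randomness are decoupled.

The `scenario_abrolhos_like` bundle adds juvenile hotspot structure
(elevated rugosity and grazing substrate at TIMB, PPAR, PABR) and a latent
trend for PABR that turns upward from 2006 while all other locations
decline. The scenario is structural, not calibrated: no attempt is made to
match the real programme's empirical distributions, so location-level
outcomes (e.g. which non-hotspot location draws a high spatial-field
value) vary with the seed.

## Problem sizes and what the tests show

Statistical tests run at stated, seeded problem sizes: permutation-ANOVA
calibration uses 500 null datasets (6 × 30 observations, 999 permutations);
hurdle coefficient coverage uses 50 replicates of n = 500 continuous-mode
censuses with the field off; selection recovery uses 20 replicates of
n = 600 with 2 true (±1) and 4 null predictors; trend-model selection uses
50 RW1-generated series (T = 20, τ = 4, level log 20); the acceptance
script uses slightly smaller replicate counts to finish in ~2 minutes.
Passing these shows the machinery is correctly calibrated and recovers
known structure under the generator's assumptions — iid exchangeability
within locations, a correctly specified hurdle likelihood, a static
spatial field. It does not show robustness to real-data features the
generator omits: spatial non-stationarity, observer drift over years,
preferential site placement, or measurement error in covariates.

## Known limitations

- The Matérn range is weakly identified from ~28 clustered sites; its
  posterior can sit a factor of 2–3 above the generating value while the
  field values themselves are recovered accurately. Interpret range
  estimates cautiously.
- Kriging under posterior-mean hyperparameters understates prediction
  uncertainty at unsampled cells (point predictions are unaffected to
  first order).
- The harmonic-mean CPO estimator is noisy for small posterior samples;
  LCPO differences well inside the equivalence band should not be
  over-read.
- With ~6 yearly observations per location, AR1/RW1/RW2 are often
  statistically indistinguishable; the parsimony band then decides, which
  is a modelling convention, not evidence.
- The CLI `predict` subcommand refits the model before predicting; fits
  are not serialised across invocations.
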
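# abrolhos

Statistical pipeline for reef-fish visual-census monitoring in a mosaic of
marine protected areas: where are the juvenile nurseries, and are the
populations recovering?

The package targets the kind of dataset produced by long-term stationary
visual-census programmes for an endangered, heavily fished parrotfish:
~28 reef sites nested in 6 locations under different protection regimes,
surveyed 2003–2008 (offshore reefs from 2005), with separate juvenile
(radius 2 m) and adult (radius 4 m) counts and strongly zero-inflated
juvenile densities. A seeded synthetic-data generator reproduces exactly
this structure, so every stage of the analysis is testable without any
field data.

## What it computes

**Density comparisons.** Density per census is `N / (π r²)`. Mean
densities per location are compared with a one-way permutation ANOVA
(labels permuted, `p = (1 + #{F* ≥ F}) / (iter + 1)`) and pairwise
permutation post-hoc tests with Holm adjustment, summarised as a compact
letter display.

**Juvenile hotspots — Bayesian hurdle spatio-temporal model.** Occurrence
and positive density are modelled in two stages with independent
parameters and a shared structure:

- stage 1: `presence ~ Bernoulli(logit⁻¹(Xβ + year + observer + w(s)))`
- stage 2: `density | presence ~ Gamma(a, mean = exp(Xβ' + year +
  observer' + w'(s)))`, fitted to the non-zero censuses only

where `X` holds standardized benthic covers (turf, CCA, fire coral,
macroalgae, sponge, stony coral, zoanthid) and environment (SST, SSS,
depth, rugosity, distance to land), fixed effects carry vague `N(0, 100)`
priors, and `w` is a Matérn(ν=1) Gaussian field on planar site
coordinates. Inference is a seeded adaptive Metropolis-within-Gibbs
sampler (joint adaptive block for fixed effects, preconditioned
Crank–Nicolson for the field). The combined prediction is the delta
expectation `E[density] = p̂ · μ̂`; top-quantile cells are nursery
hotspots.

**Model evaluation.** WAIC and CPO from per-observation log-likelihood
draws, RMSE / R² / Pearson r / AVEerror (mean absolute error) for
predictions; backward elimination keeps only predictors whose 95%
intervals exclude zero and ranks visited models by the WAIC + RMSE + R²
rank-sum compromise; validation by repeated random 50/50 split fits.

**Abundance trends.** Yearly counts aggregated per location (and pooled)
are modelled as `y_t ~ Poisson(exp(η_t))` with AR1, RW1 or RW2 latent
processes on `η_t`, compared by WAIC and LCPO with a parsimony rule for
equivalent support, with low-count exclusion guards and posterior
trend-direction probabilities.

## Worked example

```sh
python analysis/01_simulate.py           # synthetic survey programme
python analysis/02_density_permtests.py  # permutation tests by location
```

prints (seeded run):

```
juvenile: F = 217.37, df = 5, p = 0.0002 (iter = 5000)
life_stage location  mean_density_per_census letters
  juvenile     TIMB                 5.896154       a
  juvenile     ITAC                 2.648718       b
  juvenile     SEBG                 1.435897       c
  juvenile     PPAR                 1.123077       c
  juvenile     PABR                 0.588942       d
  juvenile     ARCH                 0.400000       d
```

i.e. juvenile densities differ strongly among locations (df = 5 across 6
locations; the smallest attainable p at 5000 iterations is 1/5001), and
the letter display groups locations that the adjusted pairwise tests
cannot separate. `analysis/03_hurdle_hotspots.py` then fits the hurdle
model (printing, e.g., a rugosity log-odds coefficient of ~0.94 with 95%
interval [0.72, 1.11] — rugose sites carry more juveniles) and flags
top-decile expected-density sites; `04_selection_crossval.py` reports the
chosen predictors and split-half validation (pooled Pearson r and
AVEerror); `05_abundance_trends.py` prints per-location trend directions —
declining everywhere except the one location whose latent trend was built
to turn upward from 2006, which the model recovers as `increasing` with
posterior certainty.

The same stages are available as a CLI over the CSV schemas
(`abrolhos simulate|permtest|fit-sdm|select|crossval|predict|trends`),
each writing a `manifest.json` with input digests and the config snapshot.

## Layout

- `src/abrolhos/` — library: `survey` (data model, density arithmetic,
  CSV I/O), `perm_tests`, `hurdle_sdm`, `spatial`, `model_eval`,
  `trend_models`, `synthetic_data`, `samplers`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — unit, property and statistical acceptance tests.
- `docs/methods.md` — model details, priors, numerical choices and
  limitations.
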
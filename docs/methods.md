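# Methods

This note documents the models implemented in `mortproj`, the default
choices and why they were made, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Data model and conventions

All computation happens on complete grids for one sex: `I` age bands of
common width `C` years (the documented configuration is six ten-year bands
35-44 … 85+, the top band open-ended) by `J` consecutive calendar years.
Cells hold integer death counts `D` and positive person-year exposures `N`
(mid-year populations — the only exposure measure such data provide).

The central death rate is `m = D/N`. The death probability is
`q = 1 − exp(−m)`, the constant-hazard-within-interval conversion, so
`0 ≤ q < 1` and `q ≤ m` hold for every cell. This single convention
bridges the Lee-Carter side (which models `log m`) and the Bayesian APC
side (which models `logit q`); at the rates relevant here the difference
is second order in `m`. Age bands are closed-open `[lower, lower + C)`;
the open-ended top band is treated as one ordinary group, since nothing in
the data constrains its internal exposure distribution. Period indices are
1-based internally so the cohort bookkeeping below stays readable.

## Lee-Carter

`log m[x,t] = a_x + b_x k_t + e_{xt}` with `Σ_x b_x = 1`, `Σ_t k_t = 0`.

- `a_x` is the row mean of log rates; `(b, k)` are the first singular pair
  of the centred log-rate matrix, rescaled to the normalisation. A
  surface with no time variation is not an error: it yields `k ≡ 0` and
  uniform loadings.
- Second stage: each `k_t` is re-estimated so that predicted total deaths
  given that year's exposures match the observed total (solved on the log
  scale with `logsumexp` + Brent's method for overflow safety). This is
  one of the standard variants; the fit records it in `adjustment_`. On
  degenerate surfaces with mixed-sign loadings an exact root may not
  exist; the closest achievable total is used instead.
- Zero-death cells get +0.5 deaths before logging (configurable,
  `zero_adjust`); real national-level series rarely need this but
  synthetic small-exposure surfaces do.
- The index forecast is a random walk with drift — `drift =
  (k_J − k_1)/(J − 1)`, innovation variance from the mean squared
  residual of the differences — the canonical ARIMA(0,1,0)-with-constant
  choice. Interval bounds are 2.5/97.5 percentiles over simulated paths;
  at horizon `h` the 95% band half-width on the log scale is
  `1.96 σ √h |b_x|`, which the tests verify by simulation.
- Jump-off defaults to the last **observed** log rates (flag
  `jump_off="fitted"` switches to `a + b k_J`). Continuity with the data
  at the forecast origin was judged more important than internal
  consistency with the fitted surface; the flag records that this was a
  genuinely open choice.
- Grouped (10-year) rates are fitted directly. A pre-smoothing hook can
  be applied upstream by fitting on a smoothed `RateSurface`; no spline
  smoother is built in, because its knots and penalty would be arbitrary
  here and smoothing does not change the comparison logic between models.

## Bayesian age-period-cohort model

```
D[i,j] ~ Binomial(N[i,j], q[i,j])
logit q[i,j] = mu + theta_i + phi_j + psi_k (+ z_ij),  k = C(I − i) + j
```

`i = 1` is the youngest band; the observed window carries
`K = C(I − 1) + J` cohort parameters (83 in the documented 6 × 33, C = 10
configuration). The binomial likelihood (rather than Poisson) matches the
"probability" reading of the modelled quantity; with the exposures used
here the two are practically indistinguishable.

Priors: intrinsic Gaussian random walks of order 1 or 2 per block
(default RW2 everywhere — the order whose predictive distribution
continues a local linear trend, which is what a trend-continuation
forecast means), with `Gamma(1, 5e-5)` shape/rate hyperpriors on the
block precisions (weakly informative; configurable). The optional
heterogeneity field `z` is i.i.d. `N(0, 1/τ_z)` with its own Gamma
hyperprior. Cohorts supported by few cells (extreme `k`) get the same
prior as the rest — no ad-hoc shrinkage.

### Identifiability and gauges

The likelihood identifies only the linear predictor: constants trade
between `mu` and block means, and one linear direction trades jointly
between the period slope, the cohort slope and a compensating age slope.
The package's canonical gauge sets every block mean to zero and removes
the cohort block's linear component, assigning the inseparable trend to
the period block — the gauge in which stored draws are reported. An
alternative "age-detrended" gauge is available in `decompose_effects`.
Both maps are idempotent, leave the linear predictor bitwise unchanged up
to rounding, and map an entire equivalence class to one representative.
Forecasts canonicalise first; for RW2 blocks the forecast is provably
invariant to the gauge anyway (linear continuation commutes with the
gauge group), and canonicalising makes RW1 forecasts well-defined too.

### Sampler

Metropolis-within-Gibbs:

- Effect blocks: single-site adaptive random-walk Metropolis, vectorised
  by colouring — components of a block at distance ≥ order + 1 are
  conditionally independent given the rest (the RW structure matrix is
  banded and the likelihood touches disjoint cells), so each block
  updates in `order + 1` parallel sweeps.
- `mu`: scalar Metropolis with a flat prior; `z`: one vectorised
  elementwise Metropolis sweep; precisions: exact Gamma Gibbs draws with
  shape `a + rank(R)/2` (rank `n −` order).
- Gauge fixing during the run uses exact translations along directions in
  which both the likelihood and the priors are invariant: block means are
  recentred into `mu` every iteration, and when all three blocks are RW2
  the joint linear translation is applied as well (for RW1 blocks that
  direction is penalised by the prior, so the posterior is already proper
  along it and no translation is needed). These translations preserve
  the target exactly; they are not approximations.
- Step sizes initialise from the empirical Fisher information, adapt
  every 50 iterations during burn-in towards ~40% acceptance, and are
  frozen afterwards (adaptation during burn-in only, so the retained
  chain is a fixed Markov kernel).

Correctness is checked against a dense grid-integration oracle on a
2-age × 3-period age-period toy with fixed precisions (`include_cohort=
False` exists exactly so that this four-dimensional integral is
feasible); posterior means agree to well under 0.02. Chains are
bit-reproducible given the seed (chain seeds are spawned from the spec
seed via `numpy.random.SeedSequence`).

Defaults: 2 chains × 8,000 iterations, 3,000 burn-in, thinning 5 — 2,000
retained draws. On the desk-scale grids this package targets (≈200 cells
with large exposures) the posterior is concentrated and 2,000 draws give
Monte-Carlo errors far below the posterior spread; a default fit takes a
few seconds on one CPU. All chain settings are constructor arguments.

### Prediction, DIC, decomposition

Prediction extends the period (and cohort) blocks draw-by-draw from their
RW predictive distributions using that draw's precision; future cells at
older ages reuse observed cohort parameters until their cohort index
leaves the fitted window, exactly as the index arithmetic dictates.
Future heterogeneity is drawn from its prior (setting it to zero would
understate predictive spread). Cell summaries are the posterior mean and
2.5/97.5 percentiles; the per-draw probability array is retained for the
scenario machinery.

DIC is `D̄ + pD` with `pD = D̄ − D(η̄)`, the deviance focus being the
cell-level linear predictor (including `z`); deviances are full binomial
log-likelihoods times −2, constants included. The effect decomposition
reports each block's share of the across-cell variance of the linear
predictor under the declared gauge.

## Scenarios and validation

- Scenario A: deaths `= q_last × N_proj` per cell (rate-based `m × N` by
  flag). It is exactly linear in the projection. Its uncertainty is
  binomial variation of counts around frozen rates — a construction of
  this package, labelled as such because published scenario-A intervals
  generally do not state theirs.
- Scenario B: the forecast's retained draws times the projection; totals
  and percent changes (vs the last observed year by default) carry
  2.5/97.5 draw percentiles. When the forecast equals frozen last-year
  probabilities the two scenarios coincide cell-by-cell — a consistency
  identity the tests enforce.
- MAPE: per stratum, `(100/T) Σ_t |obs − pred| / obs` on central rates
  (counts by flag); zero observed cells are excluded and counted. The
  per-year mean-within-stratum convention is the standard reading; the
  overall figure is the unweighted mean across strata. Model comparison
  fits each candidate on the training window, forecasts the hold-out
  window, and breaks ties by declared model order.

## Synthetic data

The generator produces binomial (optionally Poisson) counts from
`logit q = mu + theta_i + phi_j + psi_k (+ z_ij)` on the same cohort grid
the model uses, so recovery tests align one-to-one. Defaults describe the
desk-scale world used throughout the documentation and tests, chosen once
as a realistic cause-specific mortality setting:

- geometry 6 × 33 with C = 10, horizon 19 (a 1979-2011 observation window
  with a 2012-2030 projection analogue);
- baseline logits (−7.4 … −2.4), one logit unit per decade of age — an
  exponential age schedule spanning roughly 6 × 10⁻⁴ to 8 × 10⁻² yearly
  risk;
- period drift −0.04/year with quadratic deceleration 5 × 10⁻⁴ — a
  sustained decline of about 4%/year that visibly flattens late in the
  window;
- cohort effects: a detrended RW2 draw scaled to sd 0.05 (small and
  smooth; detrended because a linear cohort component is
  indistinguishable from period trend);
- per-sex populations 3.5M down to 0.3M by age, and projection growth
  rates that compound over 19 years to about +35%, +50% and +89% at
  65-74, 75-84 and 85+ — the magnitude of ageing projected for England &
  Wales — with near-flat younger bands;
- overdispersion off by default (tests switch it on at sd 0.2).

What the generator does **not** emulate: ICD coding changes and other
step artefacts, migration and cohort-size irregularities, correlated
(non-i.i.d.) overdispersion, sex-specific trend differences beyond what
separate configurations provide, and uncertainty in the population
projection itself. Passing recovery tests therefore show the estimators
work when their assumptions hold; they say nothing about robustness to
structural breaks in real series.

## Numerical choices

- Logistic log-likelihoods use `log1p`/`logaddexp` throughout; deviances
  keep full binomial constants (so only differences are comparable across
  likelihood conventions).
- The LC second stage solves on the log scale and falls back to the
  closest achievable total when no exact root exists.
- Rank-0 centred log-rate matrices (no time variation) return a flat
  index rather than an error; zero cells follow the +0.5 policy above.
- Percentile interval bounds are clamped to bracket the point estimate,
  guarding against percentile noise at small draw counts.
- Ties in model comparison go to the first-declared model.

## Limitations

- The MCMC sampler is single-site Metropolis (colour-vectorised); for
  much larger grids block updates or gradient-based samplers would mix
  better per iteration.
- DIC values depend on the deviance convention and are comparable only
  within this package, not across software.
- Scenario-A intervals reflect only binomial count noise, not rate
  uncertainty; scenario-B intervals condition on the model.
- The cohort-count identity `K = C(I−1) + J` requires `C ≤ J`; wider
  bands than the observed window leave gaps in the cohort index.
- No lifetable or years-of-life-lost computations, no cause-of-death
  mapping, and no cohort-component population projection: populations are
  exogenous inputs.
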
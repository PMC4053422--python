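# mortproj

Forecasting cause-specific mortality — and what population ageing does to
future death counts — for epidemiologists and health-service planners.

The motivating question: coronary-heart-disease death rates in many
countries have fallen continuously for decades, yet burden projections
routinely assume the decline stops at the jump-off year. With a population
ageing rapidly (death risk rises roughly exponentially with age), the two
assumptions give radically different futures. `mortproj` puts both on the
same footing:

- **Scenario A** — the conventional counterfactual: last-observed death
  rates persist unchanged and are multiplied by projected populations.
- **Scenario B** — recent declines continue, forecast by either of two
  conventional models, with the better out-of-sample performer chosen by
  hold-out MAPE.

## Models

**Lee-Carter** — `log m[x,t] = a_x + b_x k_t + e_{xt}` with the
normalisation `Σ_x b_x = 1`, `Σ_t k_t = 0`. Fitted by SVD of the centred
log-rate matrix, with the standard second-stage re-estimation of `k_t` to
match observed total deaths, and the index forecast as a random walk with
drift.

**Bayesian age-period-cohort (APC)** —

```
D[i,j] ~ Binomial(N[i,j], q[i,j])
logit q[i,j] = mu + theta_i + phi_j + psi_k (+ z_ij),   k = C(I - i) + j
```

with intrinsic random-walk (RW1/RW2) smoothing priors on the age, period
and cohort blocks, Gamma hyperpriors on their precisions, and an optional
i.i.d. Gaussian heterogeneity field `z` that absorbs overdispersion.
Estimation is Metropolis-within-Gibbs MCMC; forecasts let each block
continue along its random-walk predictive distribution (an RW2 block
continues its local linear trend). Model fit is compared by DIC. Because
only the linear predictor is identified (cohort = period − age), effects
are reported in an explicit gauge — sum-to-zero blocks with the
inseparable linear trend assigned to the period block — while forecasts
are provably gauge-invariant.

A synthetic-data module generates surfaces with exactly this structure
(exponential age schedule, decelerating period decline, small smooth
cohort effects, optional overdispersion, an ageing projected population),
so the whole pipeline is testable without any data downloads.

## Worked example

```python
import mortproj as mp

cfg = mp.SimulationConfig(seed=1)          # 6 age bands x 33 years, 19-year horizon
surface, _ = mp.simulate_surface(cfg)
proj = mp.simulate_projection(cfg)

report = mp.compare_models(
    surface,
    [("lee-carter", mp.LeeCarter()),
     ("bapc", mp.BayesianAPC()),
     ("frozen", mp.FrozenRateForecaster())],
    split_year=2001, seed=1,
)
print(report.overall, report.winner)

model = mp.BayesianAPC(seed=1).fit(surface)
forecast = model.forecast(19, seed=1)
res_a = mp.scenario_constant(surface, proj, seed=1)
res_b = mp.scenario_forecast(forecast, proj, observed=surface)
print(mp.percent_change(res_a).iloc[-1])
print(mp.percent_change(res_b).iloc[-1])
```

Output (abridged):

```
hold-out MAPE (%): {'lee-carter': 5.81, 'bapc': 2.95, 'frozen': 19.66}
winner: bapc
DIC: (2495.1, 40.7, 2454.4)
variance shares: {'age': 0.949, 'period': 0.051, 'cohort': 0.001}
scenario A 2030: +41% (40% to 42%)
scenario B 2030: -16% (-43% to 18%)
observed 2011 deaths: 89024 | A 2030: 125725 | B 2030: 74469
```

Reading it: on data simulated with a sustained but decelerating decline,
the Bayesian APC model forecasts the hold-out window about twice as
accurately as Lee-Carter and roughly seven times more accurately than
frozen rates; age explains almost all variation in the linear predictor,
then period, then cohort. Freezing rates at the jump-off year turns a
30-year decline into a projected +41% rise in deaths by 2030 — pure
population ageing — while the trend-continuing forecast projects a further
fall despite that ageing.

The same pipeline is available from the shell:

```bash
mortproj simulate --seed 1 --out data/
mortproj run --out results/          # simulate -> fit -> validate -> project
mortproj fit-bapc --surface data/surface.csv --horizon 19 --out fit/
mortproj validate --surface data/surface.csv --split-year 2001 --out report.csv
```

All inputs and outputs are long-format CSV (`sex, age_group, year, ...`);
`mortproj run` writes a `manifest.json` with seeds, versions and output
checksums so reruns are verifiably identical.

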
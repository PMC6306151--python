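# itsmc

Interrupted time-series intervention analysis for half-year injury count
data. The pipeline, end to end:

1. **Bin** event-level records (`date,location`) into stratified half-year
   counts (H1 = Jan–Jun, H2 = Jul–Dec) with an intervention boundary
   (`itsmc.data_model_io`).
2. **Naive before/after table**: per-period Poisson rates, rate differences
   and rate ratios with 95% Wald confidence intervals
   (`itsmc.naive_before_after`).
3. **ARIMA counterfactual**: log-transform the pre-intervention series, fit a
   grid of ARIMA(p,d,q) candidates by exact Gaussian ML, select the order
   minimizing pre-period one-step RMSE, and forecast the post period
   out-of-sample (`itsmc.arima_forecast`).
4. **Monte Carlo effect estimation**: log-normal draws around the forecast ×
   Poisson draws around the observed counts; per-period and average effects
   (annualized rate differences, percent changes) with percentile
   uncertainty intervals (`itsmc.mc_effect`).
5. **Power**: years of observation required for a two-group Poisson
   pre/post rate test (`itsmc.power`).
6. **Synthetic data**: latent log-scale trend + ARMA noise with Poisson
   observation and configurable step/ramp intervention effects, so every
   stage is testable without confidential data (`itsmc.synthetic_data`).
7. **Orchestration/CLI/plots** (`itsmc.cli_report`).

## Test

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), simulation-based oracle
checks, and `tests/test_acceptance.py` with one test per acceptance
criterion (the stochastic ones take a few minutes).

## CLI

```bash
# simulate a 27-period two-stratum panel
itsmc simulate --seed 1 --out panel.csv

# bin an events CSV into a panel
itsmc bin --events events.csv --out panel.csv

# naive before/after rate table
itsmc naive --panel panel.csv --out table.csv

# select + fit the pre-period ARIMA model for one stratum
itsmc fit --panel panel.csv --stratum private --out fit.json --rmse-table rmse.csv

# Monte Carlo effect estimation
itsmc effect --fit fit.json --panel panel.csv --iterations 10000 --seed 1 --out effects.json

# required observation time for a Poisson pre/post test
itsmc power --baseline 28.24 --reduction 10

# everything at once (table, RMSE tables, fits, effects, figures, run log)
itsmc report --panel panel.csv --seed 1 --outdir out/
```

All commands are deterministic under a fixed `--seed`.

## Layout

```
src/itsmc/
  data_model_io.py      events, study window, half-year panel, CSV I/O
  synthetic_data.py     latent-ARMA × Poisson panel generator
  naive_before_after.py Poisson rate table with Wald CIs
  arima_forecast.py     ACF/PACF, ML fitting, RMSE order selection, forecasts
  mc_effect.py          Monte Carlo effect summaries with percentile UIs
  power.py              Poisson pre/post sample-size calculation
  cli_report.py         pipeline orchestration, plots, click CLI
```
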
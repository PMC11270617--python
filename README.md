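# physflow

Stock-flow-consistent forecasting of physician supply from public panel
data. The package estimates age- and sex-specific effective exit rates
from age-grouped head-count panels, calibrates entry parameters
(`p_enter` and field-choice probabilities) against historical stocks,
simulates supply forward with a yearly age/exit/entry update, and scores
the result against constant-density requirement curves under demographic
scenarios and a pandemic demand-shock scenario.

## Layout

| module | role |
| --- | --- |
| `physflow.eurostat_io` | tidy CSV schemas for the five table kinds, validation, country configuration |
| `physflow.demography` | 10-year-group → single-year interpolation, net rates of change, exit rates, inflow and entrant sex split |
| `physflow.supply_model` | deterministic simulation core (`initialize`, `step`, `run`) |
| `physflow.calibration` | weighted chi-squared objective, exhaustive 0.01 grid search, projected numeric-gradient descent, validation RMSE and error propagation |
| `physflow.outcomes` | requirement curves, density gaps, Bonferroni-corrected significance, demand-shock scenario |
| `physflow.synthetic_data` | EUROSTAT-shaped synthetic country panels with known ground truth |
| `physflow.workflow` | per-country pipeline and multi-country batch runs with failure isolation |

## Model in brief

Stocks `N_i(s, a, t)` live on a (field, sex, age 25–74) grid. One year:

```
N_i(s, a+1, t+1) = (1 - gamma(s, a)) * N_i(s, a, t) + p_enter * p_i * Y(s, a+1, t+1)
```

with forced exit past age 74. `gamma` is the mean over years of
`max(0, -alpha)`, where `alpha` is the cohort net rate of change
estimated from single-year stocks interpolated out of 10-year groups.
Annual inflow `Y` (graduates + migrants) is split by the sex ratio of
the stock aged 25–34 in the last data year and spread uniformly over
entry ages 25–34; forecast years use the mean inflow of a configurable
window (default 2014–2019). Calibration minimises
`sum_i w_i ((Z_i - M_i) / Z_i)^2` with `w_i = Z_i / sum Z_i` at the last
data year (an all-years variant is available). The density gap at
horizon `T` is `(M_i - C_i) / (T * Y)` against the constant-density
requirement `C_i(t) = Z_i(anchor) * pop(t) / pop(anchor)`; the
demand-shock scenario inflates `C_i(t)` by `1 + I(t) * r(t)` with the
post-2022 risk `r` attenuated by 74% from its 20% baseline.

## CLI

```sh
physflow validate stocks.csv --kind stocks_by_age_sex
physflow rates stocks.csv --out rates.csv
physflow simulate --seed 42 --out-dir synth/
physflow calibrate --config cfg.yml --country AA --out fit.json
physflow forecast  --config cfg.yml --country AA --out run.csv
physflow gaps      --config cfg.yml --country AA --out gaps.csv
physflow run       --config cfg.yml --out-dir out/
```

`physflow run` writes per-country `fit.json`, `run.csv`, `gaps.csv`
plus a combined `table1.csv`. See the docstring of `physflow/cli.py`
for the YAML config format; `physflow simulate` emits a ready-made set
of the five input CSVs with a ground-truth sidecar.

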
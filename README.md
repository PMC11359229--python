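# deweather

Counterfactual ("business-as-usual") attribution of abrupt NO₂ emission
changes, built around the COVID-19 lockdown in Chinese provincial capitals.

When an intervention suddenly cuts emissions, the observed concentration
change mixes the intervention with weather: early 2020 in China had
unusually stagnant meteorology, so naive year-over-year comparisons
understate the lockdown's effect. This package implements the
meteorological-normalisation approach for separating the two, for air-quality
and environmental-health researchers:

* a **per-city random forest** (500 trees, 4 candidate predictors per split)
  trained on three reference winters (Dec–Apr 2016-17 … 2018-19) with
  predictors `year`, `day_julian`, `day_lunar` (days from the first day of
  the Chinese Lunar New Year holiday), wind speed, wind direction,
  temperature and relative humidity, predicting what NO₂ *would have been*
  in winter 2019-20 without lockdown; the machine-learning effect estimate is

  Δ<sub>ML</sub> = C̄<sub>obs,DLP</sub> − C̄<sub>BAU,DLP</sub>,

  over the during-lockdown period (DLP, 23 Jan – 18 Mar 2020);
* a **difference-to-difference comparator**
  C<sup>adj</sup><sub>d,DLP</sub> = (C̄<sub>2020,DLP</sub> − C̄<sub>hist,DLP</sub>) −
  (C̄<sub>2020,BLP</sub> − C̄<sub>hist,BLP</sub>), which adjusts the historical
  difference during lockdown by the same difference before lockdown;
* an **evaluation suite** headed by Willmott's index of agreement
  d = 1 − Σ(P−O)² / Σ(|P−Ō|+|O−Ō|)², plus MBE/MAE/RMSE and their
  observed-mean-normalised percentages and R²;
* a **log-linear health impact chain** RR = e<sup>βΔc</sup>,
  AF = 1 − e<sup>−βΔc</sup>, ΔMort = AF·y₀·Pop·days, with β = 0.009 (per µg/m³,
  non-accidental and cardiovascular) and 0.012 (respiratory);
* a **synthetic city generator** with seasonal, weekly and Lunar-New-Year
  emission structure, AR(1) meteorology, noise, missingness, and a *known*
  injected lockdown step — so the whole chain is testable against ground
  truth without any data download;
* the published **31-city benchmark table** of per-city reductions from both
  approaches, bundled as a fixture.

## Worked example

`examples/` contains one short script per capability. Attributing a known
injected effect (`examples/03_lockdown_attribution.py`):

```text
injected effect:               -16.0 ug/m3
machine-learning estimate:     -18.6 ug/m3 (-31% of business-as-usual)
difference-to-difference:      -16.1 ug/m3
lockdown days used:            55
```

Both estimators are signed (negative = reduction). Summarising the bundled
benchmark table (`examples/04_benchmark_table.py`):

```text
cities:                        31
mean ML reduction magnitude:   16.13 ug/m3
largest reduction:             29 ug/m3 (Wuhan)
smallest reduction:            5.0 ug/m3 (Haikou)
cities with a reduction:       31/31
R2 between the approaches:     0.43
```

All 31 capitals show lockdown reductions; the moderate correlation between
the two approaches reflects exactly the meteorological adjustment the
forest makes and the simpler estimator cannot.

A thin CLI wraps the same pipeline: `deweather simulate` (synthetic cohort +
truth table), `deweather run` (full pipeline to delimited outputs and a JSON
summary), `deweather table2` (benchmark summary), `deweather metrics` and
`deweather health` (ad-hoc scoring / HIA). All stages are driven by one YAML
config and one global seed.

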
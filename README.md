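# fruitflux

Fruit transpiration modelling from standard weather-station data and
gravimetric fruit-weighing campaigns.

The core model is Fick's law for water-vapour flux from a fruit surface,

```
E = G * dPw
```

where `E` is the transpiration rate (mmol cm⁻² h⁻¹), `G` the fruit skin
conductance (mmol cm⁻² h⁻¹) and `dPw` the dimensionless mol-fraction
vapour difference between the (saturated) fruit interior and the ambient
air, computed from air temperature and relative humidity. The package
implements the full analysis around that model:

- **`fruitflux.vapour`** — physical conversions: saturated vapour pressure
  (`610.7·exp(17.4·T/(239+T))` Pa), mol-fraction driving force, fruit
  surface area from length × width, and gravimetric weight loss → molar
  flux density.
- **`fruitflux.conductance`** — inverse estimation `G = E/dPw` over
  weighing intervals paired with interval-mean weather; OLS fit of the
  power-law developmental decline `G'(τ) = α·τ^β` on the log-log scale;
  95 % confidence intervals from a bias-corrected accelerated (BCa)
  bootstrap over 80 % subsamples drawn with replacement.
- **`fruitflux.identification`** — the model-identification screen:
  per-campaign-day regressions of inferred `G` on windspeed and on solar
  radiation, with slope *t*-tests, to check whether boundary-layer or
  fruit-heating extensions are warranted.
- **`fruitflux.prediction`** — forward prediction `E' = G'(τ)·dPw` on a
  regular (e.g. 15-min) grid resampled from a weather stream, running
  cumulative transpiration per unit fruit surface area, and log-log
  comparison of predicted vs. measured rates.
- **`fruitflux.synthetic`** — deterministic generators for diurnal/seasonal
  weather streams and hourly 24-h weighing campaigns whose weight loss
  follows the forward model, with a hidden truth table for recovery tests.
- **`fruitflux.io` / `fruitflux.cli`** — validated CSV readers/writers and
  a `fruitflux` command chaining the stages.

## CLI

Each stage is a subcommand; `run-all` chains them on simulated (or
provided) inputs and writes every artifact plus a summary:

```bash
# end-to-end on synthetic data
fruitflux run-all --outdir out --seed 0

# or stage by stage
fruitflux simulate-weather --out weather.csv --seed 0
fruitflux simulate-campaign --weather weather.csv --out weighings.csv --seed 1
fruitflux estimate --weather weather.csv --weighings weighings.csv \
    --full-bloom 2022-05-23 --out observations.csv
fruitflux identify --observations observations.csv --out identification.csv
fruitflux fit --observations observations.csv --out model.txt --seed 0
fruitflux predict --model model.txt --weather weather.csv \
    --full-bloom 2022-05-23 --out series.csv --window 23 140
fruitflux compare --model model.txt --observations observations.csv --out cmp.txt
fruitflux cumulate --series series.csv --out total.txt
```

`run-all` accepts a YAML config (`--config`) with keys `paths`
(weather/weighings files), `full_bloom_date`, `pressure_Pa`,
`step_minutes`, `window`, `bootstrap` (`n_boot`, `frac`, `seed`),
`filters` (`delta_pw_min`), `identification_threshold`, and
`weather_scenario`/`campaign_scenario` overrides for the generators.

All files are plain comma-separated UTF-8 with header rows; timestamps are
ISO-8601 local civil time.

## Conventions

Areas are cm², fluxes mmol cm⁻² h⁻¹, pressures Pa, conductances
mmol cm⁻² h⁻¹; τ is real-valued days after full bloom. Atmospheric
pressure defaults to 101 325 Pa and the molar mass of water to
18.015 g mol⁻¹. Fruit temperature is assumed equal to air temperature and
total conductance equal to skin conductance — assumptions the
identification screen is designed to check.
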
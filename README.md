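# batnight

Nightly presence modelling of migratory bats at offshore platforms.

Nathusius' pipistrelle (*Pipistrellus nathusii*) crosses the southern North
Sea during autumn migration, and ultrasonic detectors on offshore platforms
record it on a small fraction of nights.  `batnight` turns such acoustic
detection logs and hourly offshore weather records into a per-night
presence/absence analysis:

1. **Ingest** — parse detection logs to *positive minutes* (clock minutes
   with at least one recording), assign records to analysis nights
   (16:00 UTC to 16:00 UTC), parse KNMI-style hourly weather with its
   sentinel missing codes (cloud 9, wind direction 0 and 990), and build a
   gap-free hourly series per platform from the nearest weather station,
   imputing gaps from the two closest stations with data (scalar means,
   wind vector means, precipitation maxima).
2. **Covariates** — one row per (location, night): the binary response
   plus vector-averaged wind decomposed along the assumed ENE→WSW
   migration axis, nightly pressure and its night-over-night change,
   temperature, cloud cover, rain proportion, lunar phase (29.53-day cycle
   mapped to 360°), night-of-year, year and coordinates, with a Pearson
   collinearity screen.
3. **Model** — a Bernoulli GAM with logit link,

   `Y ~ Bernoulli(p)`, `logit(p) = Intercept + te(lon,lat) + s(night) +
   s(Δpressure) + s(tailwind) + s(crosswind) + s(cloud) + s_cc(lunar) +
   pressure + rain + year + α`,

   where `s(·)` are low-rank thin-plate regression splines, `s_cc` a
   cyclic cubic spline with boundary knots at 0° and 360°, `te` a tensor
   product of thin-plate marginals, fitted by penalized IRLS with
   per-term smoothing parameters chosen by a deterministic AIC-type grid
   descent.
4. **Calibration** — because presence is rare (~8% of nights) the raw fit
   predicts almost only absences; a post-fit constant **α** added to the
   linear predictor is grid-searched (0 to 2, step 0.025) to maximize
   sensitivity + specificity, with ties broken by smaller 0/1-loss then
   smaller α.
5. **Diagnostics and effects** — randomized quantile (Dunn–Smyth)
   residuals, per-term effect curves with 95% bands, and Tukey-style
   simultaneous contrasts between years.

Because the original monitoring data are not public, the package ships a
first-class synthetic-data generator (`batnight.synthetic`) that emulates
the whole campaign — platform/station network, autocorrelated hourly
weather with the sentinel codes, monitoring periods with equipment
outages, and nightly presence driven by known effect functions (seasonal
peak at night 250, tailwind optimum +2 m/s, crosswind optimum −1 m/s,
lunar modulation, west-high spatial gradient, ~7.7% prevalence) — so the
entire pipeline and its parameter recovery can be tested end to end.

## Worked example

Run the all-in-one pipeline on a synthetic campaign:

```sh
batnight run --seed 3 --out results/demo
```

which prints

```json
{
  "n_nights": 3346,
  "n_positive_nights": 301,
  "alpha": 2.0,
  "sensitivity": 0.6233333333333333,
  "specificity": 0.7778512396694215,
  "zero_one_loss": 0.23609022556390977
}
```

Read: the simulated campaign monitored 3346 location-nights in the autumn
window (nights 230–321), bats were present on 301 of them (9.0%), and the
calibration chose α at the top of the grid — the zero-inflated fit needs
the full shift to trade specificity (0.78) for usable sensitivity (0.62).
The output directory holds the night table, serialized model, per-α
calibration report, effect-curve tables, residual diagnostics, and a
manifest that reproduces the run byte-for-byte.

The same stages are available piecewise (`batnight simulate / prepare /
fit / calibrate / report`) and as library functions:

```python
from batnight import simulate_scenario, ScenarioConfig, fit_gam, evaluate_model

scenario = simulate_scenario(ScenarioConfig(seed=3))
model = fit_gam(scenario.night_table)
result = evaluate_model(model, scenario.night_table)
print(result.alpha, result.selected.sensitivity)
```

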
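# Methods

This note documents the statistical model, the engineering conventions,
the synthetic-data generator, and the numerical choices behind
`batnight`, in the spirit of a model-description vignette.

## The analysis unit and the response

The unit of analysis is a *location-night*: the 24-hour block from
16:00 UTC on day *d* to 16:00 UTC on day *d+1*, labelled by *d*.  The
response is `y = 1` if at least one acoustic recording of the target
species fell in that block at that location, else 0.  Recordings are
first deduplicated to positive minutes; the response only asks whether
any exist.  Night-of-year is the day-of-year of *d* (1 January = night
1; leap years reach 366), and the analysis is restricted to the autumn
window, nights 230–321 inclusive, where offshore migration concentrates.
A night belongs to a monitoring period iff its start date lies inside
the period (inclusive endpoints).  Partially monitored nights are not
distinguishable from full ones at this resolution; the bundled
2017–2020 monitoring schedule reproduces the campaign's total night
count to within about 0.3% under this convention, which is as close as
the convention ambiguity allows.

## Weather engineering

Hourly station records carry sentinel codes that are resolved to
missing at parse time and never stored as values: cloud class 9 (sky
invisible) and wind directions 0 (calm — the speed remains, the
direction is undefined) and 990 (variable).  Each platform uses its
nearest station (great-circle distance); where that station is missing
a value, the two closest stations *with data* for that hour are
combined — arithmetic mean for temperature, pressure and cloud, vector
mean of east/north components for wind, maximum for the 0/1
precipitation flag (conservative: rain anywhere nearby counts).  Hours
the nearest station covers are passed through bit-identically.

Nightly aggregation runs over the full 16:00→16:00 block.  Wind is
averaged as a vector: hourly components `e = speed·sin(dir)`,
`n = speed·cos(dir)` are averaged arithmetically and the nightly speed
and direction recovered from the mean vector, so opposing winds cancel
rather than inflate the mean.  The nightly mean wind is projected onto
the migration axis (default 67.5°, i.e. wind *from* ENE is a tailwind):

    tailwind  = cos(dir − 67.5°) · speed
    crosswind = sin(dir − 67.5°) · speed        (optionally negated)

`tailwind² + crosswind² = speed²` holds exactly.  The crosswind sign is
convention-dependent: the plain sine gives positive values for wind
from the SSE side of the axis, while the descriptive convention used in
reporting has positive = wind from the NNW.  Both are supported via a
`sign_flip` flag; the night-table builder defaults to the flipped
(NNW-positive) convention.  Pressure change is the nightly mean minus
the previous night's mean and is missing when the previous night was
not monitored; it is computed before the autumn window is applied so
the first window night is not artificially lost.  Rain is the nightly
proportion of hours with the precipitation flag set, in [0, 1].  Lunar
phase maps the 29.53-day synodic month to [0, 360) degrees (0 = new
moon, 180 = full moon) from a fixed reference new moon
(2000-01-06 18:14 UTC); only phase differences matter for the cyclic
smooth, so the epoch choice is immaterial.  A Pearson screen flags
covariate pairs with |r| ≥ 0.7 (configurable) and recommends dropping
the later-listed covariate — in campaign-like data this catches the
night-of-year/temperature confound, which is why temperature is not in
the default model.

## The model

    Y ~ Bernoulli(p)
    logit(p) = Intercept + te(lon, lat) + s(night) + s(Δpressure)
             + s(tailwind) + s(crosswind) + s(cloud) + s_cc(lunar)
             + pressure + rain + year + α

Smooth terms are penalized regression splines:

* **Thin-plate (1-D, low rank).**  Radial basis `|r|³/12` on up to 200
  quantile knots, eigen-truncated to the `k` leading components with
  the polynomial constraint absorbed; the penalty is the thin-plate
  energy in the truncated space, with rank `k − 2` and unpenalized null
  space {1, x}.  Defaults: k = 10 for night-of-year, k = 6 for the
  weather smooths — mgcv-like sizes scaled to a few thousand rows.
* **Cyclic cubic (lunar phase).**  k = 8 uniform knots on [0°, 360°]
  parameterized by knot values with periodic second-derivative
  continuity; the penalty is the integrated squared second derivative
  (`DᵀB⁻¹D`).  The fitted curve matches in value, slope and curvature
  at the wrap by construction.
* **Tensor product (space).**  Row-wise Kronecker product of two
  thin-plate marginals (k = 5 each, null space included), with one
  Kronecker-expanded marginal penalty — and one smoothing parameter —
  per margin, giving anisotropic spatial smoothing in lon/lat.

Every smooth is made identifiable by absorbing a sum-to-zero constraint
over the training rows into its basis, so smooths average out to zero
and the intercept carries the level; linear covariates are
mean-centered; the year factor is dummy-coded against its first level.
Penalty matrices are normalized to unit Frobenius norm so one smoothing
grid serves all terms.

**Fitting** is penalized IRLS on the Bernoulli deviance plus
`½ Σ λⱼ βᵀSⱼβ`, with step-halving so the penalized deviance never
increases, convergence at relative change < 1e-8 (max 200 iterations),
and weights floored at 1e-10.  Suspected complete separation
(|η| > 30) triggers a warning and a 1e-6 ridge rather than divergence;
degenerate responses (all zeros) therefore fit to a large negative
intercept instead of crashing.  The coefficient covariance is the
penalized-information inverse — the usual Bayesian GAM covariance —
used for all bands and contrasts.

**Smoothing parameters** are chosen per penalty by coordinate-wise
descent over a fixed log-spaced grid (10⁻² to 10⁸, 21 points, 3
passes), minimizing `deviance + 2γ·edf` with γ = 1.4.  Plain AIC
(γ = 1) occasionally undersmooths, which makes ridge-like artefacts in
flat effect regions; γ = 1.4 is the widely used correction and is the
package default.  The procedure is deterministic given data and grid.
This is deliberately *not* a REML replica: it is self-contained,
reproducible, and adequate at the few-thousand-row scale the package
targets.

**Effect curves** vary one term over a grid with every other term
contributing zero (smooths are centered; linear terms sit at their
training means; the factor at its reference level) and map Wald
intervals on η through the inverse logit, flagging grid points outside
the training range as extrapolation.  **Year contrasts** are all
pairwise differences on the log-odds scale with a simultaneous critical
value — the 95% quantile of the maximum absolute standardized contrast
under the fitted multivariate normal, estimated by seeded Monte Carlo —
the same family-wise protection a Tukey comparison gives; with two
levels it reduces to the Wald interval.  **Term significance** is
reported as approximate Wald chi-squares on the term's coefficients
with the Bayesian covariance; the penalty biases the reference
distribution, so these are labelled approximate and meant for ranking,
not strict inference.

## α calibration for zero inflation

With ~8% positive nights the fitted model classifies nearly everything
as absence at the 0.5 threshold: specificity near 1, sensitivity poor.
The calibration adds a constant α to the linear predictor *after*
fitting and grid-searches 0 to 2 in steps of 0.025 (81 values),
choosing the α that maximizes sensitivity + specificity, ties broken by
smaller 0/1-loss and then smaller α.  Sensitivity is non-decreasing and
specificity non-increasing in α for any data set, so the search is a
well-behaved trade; the selection is deterministic, permutation
invariant, and reproduced exactly by a brute-force loop.  Two
alternative orderings (`loss_then_youden`, `min_abs_diff`) and the
threshold are configurable.  Calibration is in-sample by design — it is
a presentation adjustment of an already-fitted model, not a predictive
claim; a held-out protocol would be the next step for honest
classification metrics.

**Residual diagnostics** use randomized quantile residuals: a uniform
draw on the probability interval the observed outcome occupies under
the fitted Bernoulli distribution, mapped through the standard-normal
quantile.  Under a correctly specified model they are exactly standard
normal; they are seeded and reproducible.

## The synthetic campaign

The generator emulates the monitoring campaign at its published scale:
13 platforms and 8 weather stations uniform in a southern North Sea box
(2.5–5.0°E, 51.5–53.5°N), three seasons (2018–2020) of hourly weather
from 1 August to 25 November, monitoring from ~10 August to ~20
November with start/stop jitter and a 50% chance of one 5–25-day
equipment outage per location-season — yielding ≈3200 autumn nights, on
the order of the real campaign.  Weather: wind as AR(1) on east/north
components (hourly autocorrelation 0.95, stationary sd 3 m/s per
component), pressure as a mean-reverting walk around 1013 hPa
(sd 2.5 hPa), temperature a seasonal sinusoid plus AR noise, cloud an
integer 0–8 tied to the pressure anomaly, precipitation Bernoulli given
cloud; missing values are injected at 1–3% per variable and written
with the sentinel codes so the parser path is exercised.

Nightly presence follows the analysis model's own structure with
stylized effect shapes — a Gaussian seasonal bump (peak night 250,
sd 18 nights, height 2 logits), concave quadratics in tailwind
(optimum +2 m/s, curvature 0.06 logits per (m/s)²) and crosswind
(optimum −1 m/s, curvature 0.05), a 0.5-logit cosine in lunar phase
with maximum at 45° (minimum near 225°, between full moon and last
quarter), a −0.5 logit/°E longitude gradient (west high), and year
offsets (0, −0.3, −0.8) depressing the final season.  Shapes are
stylized by intent: only the qualitative features — optimum positions,
signs, rough magnitudes — are encoded, not digitized curves.  The
intercept is auto-tuned by bisection so the expected prevalence matches
the 7.7% target within 0.002; one seed fixes network, weather, periods,
response and the back-filled detection log (1–5 positive minutes per
positive night, ~8% non-target-species rows, ~7.8% feeding-buzz flags)
bit-for-bit.

What passing recovery tests show — and what they do not: on 20 seeded
campaigns the fitted effect-curve maxima recover the tailwind optimum
within ±0.75 m/s and the seasonal peak within ±10 nights in ≥90% of
seeds, so the estimator is consistent with its own generating model at
campaign scale.  Real data add everything the generator omits:
detector sensitivity drift, species misclassification, spatially
correlated weather error, non-quadratic wind responses, and
day-to-day dependence beyond the covariates.  Recovery here validates
the machinery, not the ecology.

## Numerical conventions and limitations

* Directions are meteorological from-directions in (0°, 360]; 0 is a
  missing code, 360 is north.  A zero mean wind vector leaves the
  direction undefined and both wind components are set to 0.
* Complete-case handling: rows missing any model covariate (chiefly the
  first night after an outage, whose pressure change is undefined) are
  dropped at design assembly with a logged count, and the same rule is
  applied before calibration and diagnostics.
* Ties in the α search resolve toward smaller loss, then smaller α;
  grid values are rounded to 6 decimals so 0.025 steps are exact.
* Reported percentages round half away from zero to one decimal.
* The λ grid descent is a greedy coordinate search; with strongly
  correlated penalties it can stop in a local optimum of the criterion.
  The grid bounds (10⁻²–10⁸) act as soft bounds on attainable
  smoothness.
* The spatial tensor smooth is an interpolating surface over 13 sites;
  it absorbs broad spatial trend, not fine-scale autocorrelation.
* Monte-Carlo simultaneous intervals use 100 000 draws by default;
  the critical value has ~0.005 quantile noise at that size.
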
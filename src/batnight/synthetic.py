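"""Synthetic stand-ins for the offshore monitoring inputs.

No public archive of the acoustic logs or platform metadata exists, so
this module generates complete, statistically plausible replacements:
a platform/station network in a southern North Sea bounding box, hourly
station weather with realistic autocorrelation and the sentinel missing
codes of the ingest dialect, monitoring periods with equipment gaps, and
nightly presence driven by *known* effect functions, so that parameter
recovery can be verified end-to-end.

The presence model mirrors the analysis model: on the logit scale, an
intercept (auto-tuned so the expected prevalence matches a target, 7.7%
of nights by default) plus a Gaussian seasonal bump peaking in early
September, concave quadratics in tailwind (optimum +2 m/s) and crosswind
(optimum -1 m/s, i.e. light wind from the SSE under the package's sign
convention), a cosine lunar modulation with its minimum between full
moon and last quarter, a west-high linear gradient in longitude, and
per-year offsets with a depressed final year.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit

from . import covariates as cov
from . import ingest

__all__ = ["SyntheticTruth", "ScenarioConfig", "Scenario",
           "simulate_network", "simulate_weather", "simulate_periods",
           "true_linear_predictor", "simulate_presence", "simulate_scenario"]


@dataclass
class SyntheticTruth:
    """Known effect functions driving the simulated nightly presence."""

    intercept: float = float("nan")        # tuned by simulate_presence
    seasonal_peak: float = 250.0           # night-of-year of the bump maximum
    seasonal_width: float = 18.0           # Gaussian sd, nights
    seasonal_height: float = 2.0           # logit units at the peak
    tailwind_optimum: float = 2.0          # m/s
    tailwind_curvature: float = 0.06       # logit drop per (m/s)^2 off-optimum
    crosswind_optimum: float = -1.0        # m/s (negative = from the SSE)
    crosswind_curvature: float = 0.05
    lunar_amplitude: float = 0.5           # logit units
    lunar_phase_max: float = 45.0          # degrees of maximal presence
    spatial_slope: float = -0.5            # logit per degree east (west high)
    reference_lon: float = 3.75
    year_offsets: dict = field(default_factory=lambda: {2018: 0.0, 2019: -0.3,
                                                        2020: -0.8})
    target_prevalence: float = 0.077

    def __post_init__(self):
        if not (self.seasonal_width > 0):
            raise ValueError("seasonal width must be positive")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target prevalence must lie in (0, 1)")


@dataclass
class ScenarioConfig:
    """Shape of one simulated monitoring campaign."""

    n_locations: int = 13
    n_stations: int = 8
    lon_range: tuple[float, float] = (2.5, 5.0)
    lat_range: tuple[float, float] = (51.5, 53.5)
    years: tuple[int, ...] = (2018, 2019, 2020)
    coverage_start: tuple[int, int] = (8, 1)    # weather starts 1 Aug
    coverage_end: tuple[int, int] = (11, 25)    # weather ends 25 Nov
    period_start: tuple[int, int] = (8, 10)     # monitoring from ~10 Aug
    period_end: tuple[int, int] = (11, 20)      # ... to ~20 Nov
    gap_probability: float = 0.5                # chance of one outage per season
    gap_length: tuple[int, int] = (5, 25)       # outage length range, days
    missing_rates: dict = field(default_factory=lambda: {
        "wind_dir": 0.02, "wind_speed": 0.01, "temperature": 0.01,
        "pressure": 0.01, "cloud": 0.03, "precip": 0.01})
    wind_ar: float = 0.95                       # hourly AR(1) coefficient
    wind_sd: float = 3.0                        # stationary sd per component, m/s
    seed: int = 0


@dataclass
class Scenario:
    """Everything one seed generates."""

    config: ScenarioConfig
    truth: SyntheticTruth
    platforms: pd.DataFrame
    stations: pd.DataFrame
    weather: pd.DataFrame
    periods: pd.DataFrame
    night_table: pd.DataFrame
    detections: pd.DataFrame
    probabilities: np.ndarray


def simulate_network(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Platform and weather-station coordinate tables, uniform in the box."""
    if config.n_locations < 1 or config.n_stations < 1:
        raise ValueError("need at least one platform and one station")
    if config.lon_range[0] >= config.lon_range[1] or \
       config.lat_range[0] >= config.lat_range[1]:
        raise ValueError("degenerate bounding box")
    rng = np.random.default_rng(config.seed)
    def draw(n, prefix):
        return pd.DataFrame({
            "station_id": [f"{prefix}{i+1:02d}" for i in range(n)],
            "lon": rng.uniform(*config.lon_range, size=n),
            "lat": rng.uniform(*config.lat_range, size=n),
        })
    platforms = draw(config.n_locations, "P")
    stations = draw(config.n_stations, "W")
    return platforms, stations


def _season_hours(year: int, config: ScenarioConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(date(year, *config.coverage_start), tz="UTC")
    end = pd.Timestamp(date(year, *config.coverage_end), tz="UTC") \
        + pd.Timedelta(hours=23)
    return pd.date_range(start, end, freq="h")


def _ar1(rng, n, phi, sd):
    """Stationary AR(1) path of length n with stationary sd ``sd``."""
    innov_sd = sd * np.sqrt(1 - phi ** 2)
    eps = rng.normal(0, innov_sd, size=n)
    eps[0] = rng.normal(0, sd)  # stationary start
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_weather(config: ScenarioConfig, stations: pd.DataFrame) -> pd.DataFrame:
    """Hourly weather for every station over the configured seasonal windows.

    Wind is an AR(1) process on the east/north components (hourly
    autocorrelation 0.95, stationary sd 3 m/s per component by default);
    pressure is a mean-reverting walk around 1013 hPa; temperature a
    seasonal sinusoid plus AR noise; cloud an integer 0-8 tied to the
    pressure anomaly; precipitation a Bernoulli flag tied to cloud.
    Missing values (NaN) are injected at the configured per-variable
    rates; writing the table with :func:`batnight.ingest.write_weather`
    encodes them with the sentinel codes the parser resolves.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    frames = []
    for sid in stations["station_id"]:
        for year in config.years:
            hours = _season_hours(year, config)
            n = len(hours)
            e = _ar1(rng, n, config.wind_ar, config.wind_sd)
            nc = _ar1(rng, n, config.wind_ar, config.wind_sd)
            speed = np.hypot(e, nc)
            direction = np.degrees(np.arctan2(e, nc)) % 360.0
            direction[direction == 0.0] = 360.0

            press = 1013.0 + _ar1(rng, n, 0.98, 2.5)
            doy = hours.dayofyear.to_numpy()
            temp = (10.0 + 7.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
                    + _ar1(rng, n, 0.9, 2.0))
            cloud_latent = 4.0 - 0.35 * (press - 1013.0) + rng.normal(0, 1.5, n)
            cloud = np.clip(np.round(cloud_latent), 0, 8)
            precip_p = np.clip(0.01 + 0.05 * cloud, 0, 0.9)
            precip = (rng.uniform(size=n) < precip_p).astype(float)

            df = pd.DataFrame({
                "station_id": sid, "timestamp": hours,
                "wind_dir": direction, "wind_speed": speed,
                "temperature": temp, "pressure": press,
                "cloud": cloud, "precip": precip,
            })
            for var, rate in config.missing_rates.items():
                if rate > 0:
                    mask = rng.uniform(size=n) < rate
                    df.loc[mask, var] = np.nan
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_periods(config: ScenarioConfig, platforms: pd.DataFrame) -> pd.DataFrame:
    """Monitoring periods per location-year with start/stop jitter and outages."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    rows = []
    for loc in platforms["station_id"]:
        for year in config.years:
            start = date(year, *config.period_start) + \
                timedelta(days=int(rng.integers(0, 8)))
            end = date(year, *config.period_end) - \
                timedelta(days=int(rng.integers(0, 8)))
            if rng.uniform() < config.gap_probability:
                glen = int(rng.integers(config.gap_length[0], config.gap_length[1] + 1))
                span = (end - start).days
                g0 = start + timedelta(days=int(rng.integers(5, max(6, span - glen - 5))))
                g1 = g0 + timedelta(days=glen)
                rows.append({"location_id": loc, "start_date": start,
                             "end_date": g0 - timedelta(days=1)})
                if g1 < end:
                    rows.append({"location_id": loc, "start_date": g1,
                                 "end_date": end})
            else:
                rows.append({"location_id": loc, "start_date": start, "end_date": end})
    return pd.DataFrame(rows)


def true_linear_predictor(table: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """The known logit-scale signal for each night row (including intercept)."""
    night = table["night_in_year"].to_numpy(float)
    tail = table["tailwind"].to_numpy(float)
    cross = table["crosswind"].to_numpy(float)
    phase = table["lunar_phase"].to_numpy(float)
    lon = table["lon"].to_numpy(float)
    years = table["year"].to_numpy()
    eta = (truth.seasonal_height
           * np.exp(-0.5 * ((night - truth.seasonal_peak) / truth.seasonal_width) ** 2)
           - truth.tailwind_curvature * (tail - truth.tailwind_optimum) ** 2
           - truth.crosswind_curvature * (cross - truth.crosswind_optimum) ** 2
           + truth.lunar_amplitude * np.cos(np.radians(phase - truth.lunar_phase_max))
           + truth.spatial_slope * (lon - truth.reference_lon)
           + np.array([truth.year_offsets.get(int(y), 0.0) for y in years]))
    intercept = truth.intercept if np.isfinite(truth.intercept) else 0.0
    return eta + intercept


def simulate_presence(night_table: pd.DataFrame, truth: SyntheticTruth,
                      seed: int) -> tuple[np.ndarray, SyntheticTruth, np.ndarray]:
    """Draw the nightly response with the intercept tuned to the target prevalence.

    The intercept is found by bisection so that the *expected* prevalence
    ``mean(expit(eta + c))`` matches ``truth.target_prevalence`` within
    0.002; the realized positive share then fluctuates binomially around
    it.  Returns ``(y, truth_with_intercept, probabilities)``.
    """
    base = true_linear_predictor(night_table, truth) - (
        truth.intercept if np.isfinite(truth.intercept) else 0.0)

    def prevalence(c):
        return float(np.mean(expit(base + c)))

    lo, hi = -25.0, 10.0
    if not (prevalence(lo) < truth.target_prevalence < prevalence(hi)):
        raise ValueError("cannot bracket the target prevalence; "
                         "effect sizes or target out of range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < truth.target_prevalence:
            lo = mid
        else:
            hi = mid
        if abs(prevalence(mid) - truth.target_prevalence) < 2e-4:
            break
    intercept = 0.5 * (lo + hi)
    tuned = SyntheticTruth(**{**asdict(truth), "intercept": intercept})
    p = expit(base + intercept)
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=len(p)) < p).astype(int)
    return y, tuned, p


def _synthesize_detections(night_table: pd.DataFrame, seed: int,
                           other_species_share: float = 0.08,
                           feeding_buzz_rate: float = 0.078) -> pd.DataFrame:
    """Back-fill a detection log consistent with the simulated nightly response.

    Each positive night receives 1-5 positive minutes at plausible night
    hours; a share of non-target-species rows and feeding-buzz flags are
    added so the species filter and summaries are exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    rows = []
    for r in night_table.loc[night_table["y"] == 1].itertuples():
        n_min = int(rng.integers(1, 6))
        offsets = rng.choice(np.arange(4 * 60, 14 * 60), size=n_min, replace=False)
        base = pd.Timestamp(r.night_start_date, tz="UTC") \
            + pd.Timedelta(hours=ingest.NIGHT_START_HOUR)
        for off in sorted(offsets):
            rows.append({
                "location_id": r.location_id,
                "timestamp": base + pd.Timedelta(minutes=int(off),
                                                 seconds=int(rng.integers(0, 60))),
                "species": "Pnat",
                "feeding_buzz": bool(rng.uniform() < feeding_buzz_rate),
            })
    det = pd.DataFrame(rows, columns=["location_id", "timestamp", "species",
                                      "feeding_buzz"])
    # sprinkle in other species so the filter has something to drop
    n_other = int(round(len(det) * other_species_share / (1 - other_species_share)))
    if n_other and len(night_table):
        idx = rng.integers(0, len(night_table), size=n_other)
        sub = night_table.iloc[idx]
        other = pd.DataFrame({
            "location_id": sub["location_id"].to_numpy(),
            "timestamp": [pd.Timestamp(d, tz="UTC")
                          + pd.Timedelta(hours=ingest.NIGHT_START_HOUR)
                          + pd.Timedelta(minutes=int(m))
                          for d, m in zip(sub["night_start_date"],
                                          rng.integers(4 * 60, 14 * 60, n_other))],
            "species": rng.choice(["Ppip", "Nnoc"], size=n_other),
            "feeding_buzz": False,
        })
        det = pd.concat([det, other], ignore_index=True)
    return det.sort_values(["location_id", "timestamp"]).reset_index(drop=True)


def simulate_scenario(config: ScenarioConfig | None = None,
                      truth: SyntheticTruth | None = None,
                      season_window: tuple[int, int] = cov.SEASON_WINDOW,
                      migration_dir: float = cov.MIGRATION_DIR,
                      crosswind_flip: bool = True) -> Scenario:
    """Generate the full fixture set for one seed: network, weather, nights, y.

    The night table is assembled through the real ingest/covariate path
    (imputation included), then the response is drawn from the known
    effect functions and a detection log is synthesized backwards from it.
    """
    config = config or ScenarioConfig()
    truth = truth or SyntheticTruth()
    platforms, stations = simulate_network(config)
    weather = simulate_weather(config, stations)
    periods = simulate_periods(config, platforms)

    weather_series = {}
    for r in platforms.itertuples():
        hours = _required_hours(periods.loc[periods["location_id"] == r.station_id],
                                config)
        weather_series[r.station_id] = ingest.impute_weather(
            (r.lon, r.lat), stations, weather, hours)

    empty_minutes = ingest.to_positive_minutes(
        pd.DataFrame(columns=["location_id", "timestamp"]))
    table = cov.build_night_table(empty_minutes, weather_series, periods,
                                  platforms, season_window=season_window,
                                  migration_dir=migration_dir,
                                  crosswind_flip=crosswind_flip)
    y, tuned, p = simulate_presence(table, truth, config.seed)
    table = table.copy()
    table["y"] = y
    detections = _synthesize_detections(table, config.seed)
    return Scenario(config=config, truth=tuned, platforms=platforms,
                    stations=stations, weather=weather, periods=periods,
                    night_table=table, detections=detections, probabilities=p)


def _required_hours(loc_periods: pd.DataFrame, config: ScenarioConfig) -> pd.DatetimeIndex:
    pieces = []
    for r in loc_periods.itertuples():
        start = pd.Timestamp(r.start_date, tz="UTC") \
            + pd.Timedelta(hours=ingest.NIGHT_START_HOUR)
        end = pd.Timestamp(r.end_date, tz="UTC") \
            + pd.Timedelta(hours=ingest.NIGHT_START_HOUR + 23)
        pieces.append(pd.date_range(start, end, freq="h"))
    idx = pieces[0]
    for piece in pieces[1:]:
        idx = idx.union(piece)
    return idx
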
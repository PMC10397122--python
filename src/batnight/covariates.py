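"""Per-night covariate engineering for the presence/absence analysis.

Each analysis row is one (location, night) with the binary response —
was the species recorded at least once that night — plus the nightly
weather summaries, the wind decomposition along the assumed migration
axis, lunar phase, calendar position and coordinates.

Wind is averaged as a vector: hourly (direction, speed) observations are
decomposed into east/north components, the components are averaged
arithmetically, and nightly speed and direction are recovered from the
mean vector.  The nightly mean wind is then projected onto the migration
axis (ENE -> WSW by default, i.e. wind *from* 67.5 deg is a tailwind):

    tailwind  = cos(dir - migration_dir) * speed
    crosswind = sin(dir - migration_dir) * speed

Positive tailwind means supportive wind along the migration direction.
The crosswind sign is convention-dependent; with ``sign_flip`` (the
default used by :func:`build_night_table`) positive crosswind means wind
from the NNW side of the axis.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .ingest import IngestError, assign_night

#: Default migration from-direction in degrees (ENE).
MIGRATION_DIR = 67.5

#: Synodic month length in days used for the 360-degree lunar phase.
SYNODIC_MONTH = 29.53

#: Reference new moon (UTC): 2000-01-06 18:14.  Only phase differences
#: matter for the cyclic smoother, so any accurately known new moon works.
NEW_MOON_EPOCH = pd.Timestamp("2000-01-06 18:14", tz="UTC")

#: Autumn analysis window in night-of-year numbers (inclusive).
SEASON_WINDOW = (230, 321)

NIGHT_TABLE_COLUMNS = [
    "location_id", "night_start_date", "night_in_year", "year", "y",
    "tailwind", "crosswind", "pressure", "pressure_change", "temperature",
    "cloud", "rain", "lunar_phase", "lon", "lat",
]


def night_index(night_start_date: date) -> int:
    """1-based day-of-year of the night's start date (366 in leap years)."""
    return night_start_date.timetuple().tm_yday


def vector_average_wind(wind_dir, wind_speed) -> tuple[float, float]:
    """Vector-average hourly wind into one (speed, direction) pair.

    Hours where the speed is missing, or the direction is missing at
    non-zero speed, are ignored.  Returns ``(speed, dir)`` with the
    direction in (0, 360] degrees, or NaN direction when the mean vector
    has zero length (opposing winds cancel).

    Raises
    ------
    ValueError
        If no usable hour remains (an upstream imputation failure).
    """
    d = np.asarray(wind_dir, dtype=float)
    s = np.asarray(wind_speed, dtype=float)
    usable = ~np.isnan(s) & (~np.isnan(d) | (s == 0))
    if not usable.any():
        raise ValueError("vector_average_wind: all hours missing; imputation failed upstream")
    d = d[usable]
    s = s[usable]
    rad = np.radians(np.where(np.isnan(d), 0.0, d))
    e = np.where(s == 0, 0.0, s * np.sin(rad)).mean()
    n = np.where(s == 0, 0.0, s * np.cos(rad)).mean()
    speed = float(np.hypot(e, n))
    if speed < 1e-12:            # opposing vectors cancel: direction undefined
        return 0.0, float("nan")
    direction = float(np.degrees(np.arctan2(e, n)) % 360.0)
    if direction == 0.0:
        direction = 360.0
    return speed, direction


def tailwind_component(avg_dir: float, avg_speed: float,
                       migration_dir: float = MIGRATION_DIR) -> float:
    """Signed wind component along the migration axis (positive = supportive)."""
    return float(np.cos(np.radians(avg_dir - migration_dir)) * avg_speed)


def crosswind_component(avg_dir: float, avg_speed: float,
                        migration_dir: float = MIGRATION_DIR,
                        sign_flip: bool = False) -> float:
    """Signed wind component perpendicular to the migration axis.

    As printed, ``sin(dir - migration_dir) * speed`` is positive for wind
    from the SSE side of the ENE axis; ``sign_flip`` negates it so that
    positive values mean wind from the NNW, the verbal convention used
    when describing the crosswind effect.
    """
    value = float(np.sin(np.radians(avg_dir - migration_dir)) * avg_speed)
    return -value if sign_flip else value


def pressure_change(night_pressures: pd.Series) -> pd.Series:
    """Night-over-night change of the nightly mean pressure.

    ``night_pressures`` is indexed by night start date (ordered).  The
    change for night *t* is defined only when night *t-1* is present:
    the first night, and any night following a gap, gets NaN.
    """
    idx = pd.Index(night_pressures.index)
    prev_dates = pd.Index([d - timedelta(days=1) for d in idx])
    prev = night_pressures.reindex(prev_dates)
    return pd.Series(night_pressures.to_numpy(float) - prev.to_numpy(float), index=idx)


def lunar_phase(when) -> float:
    """Lunar phase in degrees [0, 360): 0 = new moon, 180 = full moon.

    Accepts a date or datetime; a naive datetime is taken as UTC.  The
    phase is the elapsed fraction of a 29.53-day synodic month since a
    reference new moon, scaled to 360 degrees.
    """
    if isinstance(when, datetime):
        ts = pd.Timestamp(when)
        ts = ts.tz_localize("UTC") if ts.tzinfo is None else ts.tz_convert("UTC")
    elif isinstance(when, date):
        ts = pd.Timestamp(when, tz="UTC")
    else:
        ts = pd.Timestamp(when)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
    days = (ts - NEW_MOON_EPOCH) / pd.Timedelta(days=1)
    return float((days / SYNODIC_MONTH % 1.0) * 360.0)


def build_night_table(positive_minutes: pd.DataFrame,
                      weather_series: dict[str, pd.DataFrame],
                      periods: pd.DataFrame,
                      coordinates: pd.DataFrame,
                      season_window: tuple[int, int] = SEASON_WINDOW,
                      migration_dir: float = MIGRATION_DIR,
                      crosswind_flip: bool = True) -> pd.DataFrame:
    """Assemble the one-row-per-(location, night) analysis table.

    Parameters
    ----------
    positive_minutes : output of :func:`batnight.ingest.to_positive_minutes`.
    weather_series : mapping location_id -> gap-free hourly weather frame
        (indexed by UTC hour, columns as in the ingest contract), e.g. the
        output of :func:`batnight.ingest.impute_weather`.
    periods : monitoring periods with inclusive ``start_date``/``end_date``;
        a night belongs to a period iff its start date lies inside it.
    coordinates : platform coordinates (``station_id, lon, lat``).
    season_window : inclusive night-of-year window retained in the output.
    migration_dir, crosswind_flip : wind decomposition convention.

    Nightly means are taken over the full 16:00 -> 16:00 UTC block.  The
    pressure change is computed over all monitored nights before the
    seasonal window is applied, so the first window night is not
    artificially missing.
    """
    coords = coordinates.set_index("station_id")
    # nights with >=1 positive minute, per location
    if len(positive_minutes):
        pm_nights = set(zip(positive_minutes["location_id"],
                            assign_night(positive_minutes["minute"])))
    else:
        pm_nights = set()

    rows = []
    for loc, loc_periods in periods.groupby("location_id", sort=True):
        if loc not in coords.index:
            raise IngestError(f"location {loc!r} has no coordinates")
        if loc not in weather_series:
            raise IngestError(f"location {loc!r} has no weather series")
        lon = float(coords.loc[loc, "lon"])
        lat = float(coords.loc[loc, "lat"])
        wx = weather_series[loc]

        nights: list[date] = []
        for p in loc_periods.itertuples():
            d = p.start_date
            while d <= p.end_date:
                nights.append(d)
                d = d + timedelta(days=1)
        nights = sorted(set(nights))

        # nightly aggregation over the 16:00->16:00 block
        night_of_hour = np.asarray(assign_night(wx.index))
        work = wx.copy()
        d_arr = work["wind_dir"].to_numpy(float)
        s_arr = work["wind_speed"].to_numpy(float)
        usable = ~np.isnan(s_arr) & (~np.isnan(d_arr) | (s_arr == 0))
        rad = np.radians(np.where(np.isnan(d_arr), 0.0, d_arr))
        work["wind_e"] = np.where(usable, np.where(s_arr == 0, 0.0, s_arr * np.sin(rad)),
                                  np.nan)
        work["wind_n"] = np.where(usable, np.where(s_arr == 0, 0.0, s_arr * np.cos(rad)),
                                  np.nan)
        agg = work.groupby(night_of_hour).mean()

        press = agg["pressure"].reindex(nights)
        dpress = pressure_change(press)

        for d in nights:
            nidx = night_index(d)
            if not (season_window[0] <= nidx <= season_window[1]):
                continue
            if d not in agg.index:
                raise IngestError(f"no weather hours for {loc} night {d}")
            night_agg = agg.loc[d]
            e_mean, n_mean = float(night_agg["wind_e"]), float(night_agg["wind_n"])
            if np.isnan(e_mean):
                raise ValueError(f"all wind hours missing for {loc} night {d}; "
                                 "imputation failed upstream")
            speed = float(np.hypot(e_mean, n_mean))
            if speed == 0.0:
                tail, cross = 0.0, 0.0   # zero mean vector: no net wind either way
            else:
                direction = float(np.degrees(np.arctan2(e_mean, n_mean)) % 360.0) or 360.0
                tail = tailwind_component(direction, speed, migration_dir)
                cross = crosswind_component(direction, speed, migration_dir,
                                            sign_flip=crosswind_flip)
            rows.append({
                "location_id": loc,
                "night_start_date": d,
                "night_in_year": nidx,
                "year": d.year,
                "y": int((loc, d) in pm_nights),
                "tailwind": tail,
                "crosswind": cross,
                "pressure": float(press.loc[d]),
                "pressure_change": float(dpress.loc[d]),
                "temperature": float(night_agg["temperature"]),
                "cloud": float(night_agg["cloud"]),
                "rain": float(night_agg["precip"]),
                "lunar_phase": lunar_phase(d),
                "lon": lon,
                "lat": lat,
            })
    out = pd.DataFrame(rows, columns=NIGHT_TABLE_COLUMNS)
    if out.duplicated(["location_id", "night_start_date"]).any():
        raise IngestError("overlapping monitoring periods produce duplicate nights")
    return out.reset_index(drop=True)


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7) -> dict:
    """Pairwise Pearson screening of the numeric covariates.

    Returns ``{"pairs": DataFrame, "zero_variance": [names]}`` where the
    pairs frame lists every covariate pair with |r| at or above the
    threshold together with the recommendation to drop the later-listed
    covariate of the pair.
    """
    numeric = [c for c in NIGHT_TABLE_COLUMNS
               if c not in ("location_id", "night_start_date", "year", "y")
               and c in table.columns]
    data = table[numeric].dropna()
    if len(data) < 3:
        raise ValueError("collinearity_screen needs at least 3 complete rows")
    sd = data.std(ddof=1)
    zero_var = [c for c in numeric if sd[c] == 0 or not np.isfinite(sd[c])]
    usable = [c for c in numeric if c not in zero_var]
    corr = data[usable].corr(method="pearson")
    flagged = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= threshold:
                flagged.append({"covariate_1": a, "covariate_2": b, "r": r,
                                "recommend_drop": b})
    pairs = pd.DataFrame(flagged, columns=["covariate_1", "covariate_2", "r",
                                           "recommend_drop"])
    return {"pairs": pairs, "zero_variance": zero_var}
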
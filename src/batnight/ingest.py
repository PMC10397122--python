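"""Reading and regularising the raw inputs of the nightly bat-presence analysis.

Three delimited-text inputs feed the pipeline: acoustic detection logs
(one row per recording), hourly weather-station records in a KNMI-like
dialect, and small coordinate / monitoring-period tables.  This module
parses them into tidy :class:`pandas.DataFrame` containers, collapses
detections to *positive minutes* (clock minutes with at least one
recording), assigns timestamps to analysis nights (16:00 UTC to 16:00 UTC),
and produces gap-free hourly weather series per monitoring location by
nearest-station lookup with two-station imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger("batnight")

#: Hour (UTC) at which an analysis night starts and the previous one ends.
NIGHT_START_HOUR = 16

#: Columns of a parsed weather frame, in contract order.
WEATHER_VARS = ["wind_dir", "wind_speed", "temperature", "pressure", "cloud", "precip"]

DETECTION_COLUMNS = ["location_id", "timestamp", "species", "feeding_buzz"]


class IngestError(ValueError):
    """Raised when an input file violates the ingest contract."""


@dataclass
class WeatherDialect:
    """Configurable dialect of the hourly weather export.

    Defaults match the contract header
    ``station_id,timestamp,wind_dir,wind_speed,temperature,pressure,cloud,precip``.
    KNMI-style sentinel codes are resolved at parse time: cloud class 9
    (sky invisible) and wind directions 0 (calm, direction undefined) and
    990 (variable) are mapped to missing and never stored as values.
    """

    sep: str = ","
    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in ["station_id", "timestamp", *WEATHER_VARS]}
    )
    missing_tokens: tuple[str, ...] = ("", "NA", "NaN")
    cloud_missing_codes: tuple[int, ...] = (9,)
    wind_dir_missing_codes: tuple[int, ...] = (0, 990)


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

def read_detections(path, species_filter: str | None = None) -> pd.DataFrame:
    """Read an acoustic detection log.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header naming at least
        ``location_id,timestamp,species,feeding_buzz``; unknown columns are
        ignored.  Timestamps are ISO-8601 and interpreted as UTC.
    species_filter : str, optional
        When given, only rows whose ``species`` equals the filter are
        returned; the number of dropped rows is logged.

    Returns
    -------
    pandas.DataFrame
        Columns ``location_id`` (str), ``timestamp`` (tz-aware UTC),
        ``species`` (str), ``feeding_buzz`` (bool).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DETECTION_COLUMNS if c not in raw.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")
    out = raw[DETECTION_COLUMNS].copy()
    ts = pd.to_datetime(out["timestamp"], utc=True, errors="coerce", format="ISO8601")
    if ts.isna().any():
        # header is line 1, first data row line 2
        line = int(ts.index[ts.isna()][0]) + 2
        raise IngestError(
            f"{path}: unparseable timestamp {out['timestamp'].iloc[line - 2]!r} at line {line}"
        )
    out["timestamp"] = ts
    if (out["location_id"].str.len() == 0).any():
        line = int(out.index[out["location_id"].str.len() == 0][0]) + 2
        raise IngestError(f"{path}: empty location_id at line {line}")
    out["feeding_buzz"] = out["feeding_buzz"].str.lower().isin(("1", "true", "t", "yes"))
    if species_filter is not None:
        keep = out["species"] == species_filter
        dropped = int((~keep).sum())
        if dropped:
            logger.info("read_detections: dropped %d rows not matching species %r",
                        dropped, species_filter)
        out = out.loc[keep].reset_index(drop=True)
    return out


def to_positive_minutes(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse detection records to unique (location, minute) pairs.

    A positive minute is a clock minute at one location containing at least
    one recording.  Output is sorted by location then minute and is
    idempotent under re-application.
    """
    if len(records) == 0:
        return pd.DataFrame({"location_id": pd.Series(dtype=str),
                             "minute": pd.Series(dtype="datetime64[ns, UTC]")})
    ts = records["minute"] if "minute" in records.columns else records["timestamp"]
    out = pd.DataFrame({
        "location_id": records["location_id"].to_numpy(),
        "minute": pd.DatetimeIndex(ts).floor("min"),
    })
    return (out.drop_duplicates()
               .sort_values(["location_id", "minute"])
               .reset_index(drop=True))


def assign_night(timestamp):
    """Map a UTC timestamp to the calendar date labelling its analysis night.

    A night runs from 16:00 UTC on day *d* (inclusive) to 16:00 UTC on day
    *d+1* (exclusive) and is labelled *d*.  Accepts a single datetime or a
    datetime-like Series/Index; returns a ``datetime.date`` or a Series of
    dates correspondingly.
    """
    shift = timedelta(hours=NIGHT_START_HOUR)
    if isinstance(timestamp, (pd.Series, pd.DatetimeIndex)):
        shifted = pd.DatetimeIndex(timestamp) - shift
        res = pd.Series(shifted.date, index=getattr(timestamp, "index", None))
        return res
    if isinstance(timestamp, datetime):
        return (timestamp - shift).date()
    raise TypeError(f"assign_night expects a datetime or datetime series, got {type(timestamp)}")


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def read_weather(path, dialect: WeatherDialect | None = None) -> pd.DataFrame:
    """Read an hourly weather export and resolve missing-value codes.

    Returns a frame with columns ``station_id, timestamp`` plus
    :data:`WEATHER_VARS`; numeric columns are floats with NaN for missing.
    Cloud code 9 and wind-direction codes 0 / 990 become missing at parse
    time.  Duplicate station-hours are a hard error; rows are sorted so
    hours strictly increase within each station.
    """
    dialect = dialect or WeatherDialect()
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in dialect.columns.items()}
    raw = raw.rename(columns=rename)
    required = ["station_id", "timestamp", *WEATHER_VARS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")
    out = raw[required].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True, format="ISO8601")
    for var in WEATHER_VARS:
        col = out[var].where(~out[var].isin(dialect.missing_tokens), np.nan)
        out[var] = pd.to_numeric(col, errors="raise")
    out.loc[out["cloud"].isin(dialect.cloud_missing_codes), "cloud"] = np.nan
    out.loc[out["wind_dir"].isin(dialect.wind_dir_missing_codes), "wind_dir"] = np.nan
    dup = out.duplicated(["station_id", "timestamp"])
    if dup.any():
        key = out.loc[dup, ["station_id", "timestamp"]].iloc[0]
        raise IngestError(f"{path}: duplicate station-hour {key.station_id} {key.timestamp}")
    return out.sort_values(["station_id", "timestamp"]).reset_index(drop=True)


def read_stations(path) -> pd.DataFrame:
    """Read a station (or platform) coordinate table: id, lon, lat."""
    out = pd.read_csv(path)
    out.columns = [c.strip() for c in out.columns]
    id_col = out.columns[0]
    out = out.rename(columns={id_col: "station_id"})
    out["station_id"] = out["station_id"].astype(str)
    if out["station_id"].duplicated().any():
        raise IngestError(f"{path}: duplicate ids")
    if not np.isfinite(out[["lon", "lat"]].to_numpy(float)).all():
        raise IngestError(f"{path}: non-finite coordinates")
    return out[["station_id", "lon", "lat"]]


def read_periods(path) -> pd.DataFrame:
    """Read monitoring periods ``location_id,start_date,end_date`` (inclusive dates)."""
    out = pd.read_csv(path, dtype={"location_id": str},
                      parse_dates=["start_date", "end_date"])
    if (out["end_date"] < out["start_date"]).any():
        raise IngestError(f"{path}: period with end_date before start_date")
    out["start_date"] = out["start_date"].dt.date
    out["end_date"] = out["end_date"].dt.date
    return out


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in kilometres between points given in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 6371.0 * 2 * np.arcsin(np.sqrt(a))


def _first_two_filled(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per column, the first and second non-NaN entries scanning rows in order."""
    first = np.full(values.shape[1], np.nan)
    second = np.full(values.shape[1], np.nan)
    for row in values:
        have = ~np.isnan(row)
        m2 = have & ~np.isnan(first) & np.isnan(second)
        m1 = have & np.isnan(first)
        first[m1] = row[m1]
        second[m2] = row[m2]
    return first, second


def impute_weather(location_lonlat: tuple[float, float],
                   stations: pd.DataFrame,
                   weather: pd.DataFrame,
                   hours: pd.DatetimeIndex) -> pd.DataFrame:
    """Produce a gap-free hourly weather series for one monitoring location.

    For every hour and variable the value of the nearest station is used
    when present; otherwise the two closest stations *with data* for that
    hour are combined — arithmetic mean for scalar variables, a vector mean
    of east/north components (recombined to speed and direction) for wind,
    and the maximum for the 0/1 precipitation flag.  Hours the nearest
    station covers are never altered.

    Parameters
    ----------
    location_lonlat : (lon, lat) of the monitoring location in degrees.
    stations : coordinate table with ``station_id, lon, lat``.
    weather : parsed weather frame (all stations pooled).
    hours : the exact hourly index the output must cover.

    Raises
    ------
    IngestError
        If for some required hour no station reports the variable.
    """
    lon0, lat0 = location_lonlat
    dist = haversine_km(stations["lon"].to_numpy(), stations["lat"].to_numpy(), lon0, lat0)
    order = stations["station_id"].to_numpy()[np.argsort(dist, kind="stable")]

    # per-station variable matrices aligned to the requested hours
    mats = {}
    for sid in order:
        sub = weather.loc[weather["station_id"] == sid].set_index("timestamp")
        sub = sub[~sub.index.duplicated()].reindex(hours)
        mats[sid] = sub
    n = len(hours)

    def stack(var):
        return np.vstack([mats[sid][var].to_numpy(float) for sid in order])

    out = pd.DataFrame(index=hours)
    filled_from_neighbours = 0

    for var in ("temperature", "pressure", "cloud"):
        vals = stack(var)
        first, second = _first_two_filled(vals)
        if np.isnan(first).any():
            bad = hours[np.isnan(first)]
            raise IngestError(f"no station reports {var} for hour(s) {list(bad[:5])}")
        combined = np.where(np.isnan(second), first, 0.5 * (first + second))
        res = np.where(~np.isnan(vals[0]), vals[0], combined)
        filled_from_neighbours += int(np.isnan(vals[0]).sum())
        out[var] = res

    # precipitation: max of the two closest with data
    vals = stack("precip")
    first, second = _first_two_filled(vals)
    if np.isnan(first).any():
        bad = hours[np.isnan(first)]
        raise IngestError(f"no station reports precip for hour(s) {list(bad[:5])}")
    combined = np.where(np.isnan(second), first, np.maximum(first, second))
    out["precip"] = np.where(~np.isnan(vals[0]), vals[0], combined)
    filled_from_neighbours += int(np.isnan(vals[0]).sum())

    # wind: a station-hour is usable when speed is present and either the
    # direction is present or the speed is zero (calm; direction undefined)
    dir_m = np.vstack([mats[sid]["wind_dir"].to_numpy(float) for sid in order])
    spd_m = np.vstack([mats[sid]["wind_speed"].to_numpy(float) for sid in order])
    usable = ~np.isnan(spd_m) & (~np.isnan(dir_m) | (spd_m == 0))
    rad = np.radians(np.where(np.isnan(dir_m), 0.0, dir_m))
    e_m = np.where(usable, np.where(spd_m == 0, 0.0, spd_m * np.sin(rad)), np.nan)
    n_m = np.where(usable, np.where(spd_m == 0, 0.0, spd_m * np.cos(rad)), np.nan)
    e1, e2 = _first_two_filled(e_m)
    n1, n2 = _first_two_filled(n_m)
    if np.isnan(e1).any():
        bad = hours[np.isnan(e1)]
        raise IngestError(f"no station reports wind for hour(s) {list(bad[:5])}")
    e_comb = np.where(np.isnan(e2), e1, 0.5 * (e1 + e2))
    n_comb = np.where(np.isnan(n2), n1, 0.5 * (n1 + n2))
    nearest_ok = usable[0]
    e = np.where(nearest_ok, e_m[0], e_comb)
    nn = np.where(nearest_ok, n_m[0], n_comb)
    filled_from_neighbours += int((~nearest_ok).sum())
    speed = np.hypot(e, nn)
    direction = np.degrees(np.arctan2(e, nn)) % 360.0
    direction[direction == 0.0] = 360.0          # from-direction convention (0, 360]
    direction[speed == 0.0] = np.nan             # calm: direction undefined
    # pass observed nearest-station values through untouched
    speed[nearest_ok] = spd_m[0][nearest_ok]
    direction[nearest_ok] = dir_m[0][nearest_ok]
    out["wind_speed"] = speed
    out["wind_dir"] = direction

    if filled_from_neighbours:
        logger.info("impute_weather: %d cells filled from neighbouring stations "
                    "(nearest station missing)", filled_from_neighbours)
    return out[WEATHER_VARS]


# ---------------------------------------------------------------------------
# Writers (emit exactly the dialects the readers consume)
# ---------------------------------------------------------------------------

def write_detections(records: pd.DataFrame, path) -> None:
    """Write a detection log in the contract dialect (ISO-8601 UTC timestamps)."""
    out = records.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out["feeding_buzz"] = out["feeding_buzz"].astype(bool).map({True: "1", False: "0"})
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def write_weather(weather: pd.DataFrame, path,
                  dialect: WeatherDialect | None = None) -> None:
    """Write an hourly weather table, encoding missing values as the dialect does.

    Missing cloud becomes the first configured cloud sentinel (9), missing
    wind direction the last wind-direction sentinel (990); other missing
    values become the empty token.  Round-trips through
    :func:`read_weather` back to missing.
    """
    dialect = dialect or WeatherDialect()
    out = weather.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    cloud_sent = dialect.cloud_missing_codes[0]
    dir_sent = dialect.wind_dir_missing_codes[-1]
    cols = {}
    for var in WEATHER_VARS:
        vals = out[var].astype(object)
        if var == "cloud":
            vals = vals.where(out[var].notna(), cloud_sent)
        elif var == "wind_dir":
            vals = vals.where(out[var].notna(), dir_sent)
        else:
            vals = vals.where(out[var].notna(), dialect.missing_tokens[0])
        cols[var] = vals
    enc = pd.DataFrame({"station_id": out["station_id"],
                        "timestamp": out["timestamp"], **cols})
    enc.rename(columns=dialect.columns).to_csv(path, index=False, sep=dialect.sep)


def write_stations(stations: pd.DataFrame, path) -> None:
    stations[["station_id", "lon", "lat"]].to_csv(path, index=False)


def write_periods(periods: pd.DataFrame, path) -> None:
    out = periods.copy()
    out["start_date"] = out["start_date"].astype(str)
    out["end_date"] = out["end_date"].astype(str)
    out[["location_id", "start_date", "end_date"]].to_csv(path, index=False)


def night_hours(night: date) -> pd.DatetimeIndex:
    """The 24 hourly timestamps of one analysis night (16:00 d .. 15:00 d+1 UTC)."""
    start = pd.Timestamp(night, tz="UTC") + pd.Timedelta(hours=NIGHT_START_HOUR)
    return pd.date_range(start, periods=24, freq="h")
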
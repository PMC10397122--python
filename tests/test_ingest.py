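"""Parsing, positive-minute deduplication, night assignment, imputation."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batnight import ingest

UTC = timezone.utc


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDetections:
    def test_species_filter_keeps_matching_rows(self, tmp_path):
        p = _write(tmp_path, "det.csv",
                   "location_id,timestamp,species,feeding_buzz,extra\n"
                   "A,2019-09-12T22:14:05Z,Pnat,0,x\n"
                   "A,2019-09-12T22:14:59Z,Ppip,1,x\n"
                   "B,2019-09-12T22:15:00Z,Pnat,0,x\n")
        out = ingest.read_detections(p, species_filter="Pnat")
        assert len(out) == 2
        assert set(out["species"]) == {"Pnat"}
        assert str(out["timestamp"].dt.tz) == "UTC"

    def test_empty_file_with_header_gives_empty_frame(self, tmp_path):
        p = _write(tmp_path, "det.csv", "location_id,timestamp,species,feeding_buzz\n")
        assert len(ingest.read_detections(p)) == 0

    def test_majority_species_share_preserved_by_filter(self, tmp_path):
        rows = ["location_id,timestamp,species,feeding_buzz"]
        for i in range(100):
            sp = "Pnat" if i < 92 else "Nnoc"
            rows.append(f"A,2019-09-12T2{i % 2}:{i % 60:02d}:00Z,{sp},0")
        p = _write(tmp_path, "det.csv", "\n".join(rows) + "\n")
        out = ingest.read_detections(p, species_filter="Pnat")
        assert len(out) == 92

    def test_missing_column_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "det.csv", "location_id,timestamp,species\nA,x,y\n")
        with pytest.raises(ingest.IngestError, match="feeding_buzz"):
            ingest.read_detections(p)

    def test_bad_timestamp_error_names_line(self, tmp_path):
        p = _write(tmp_path, "det.csv",
                   "location_id,timestamp,species,feeding_buzz\n"
                   "A,2019-09-12T22:14:05Z,Pnat,0\n"
                   "A,not-a-time,Pnat,0\n")
        with pytest.raises(ingest.IngestError, match="line 3"):
            ingest.read_detections(p)


class TestPositiveMinutes:
    def test_truncation_and_dedup(self):
        rec = pd.DataFrame({
            "location_id": ["A"] * 3,
            "timestamp": pd.to_datetime(["2019-09-12 22:14:05",
                                         "2019-09-12 22:14:59",
                                         "2019-09-12 22:15:00"], utc=True),
        })
        out = ingest.to_positive_minutes(rec)
        assert len(out) == 2

    def test_same_minute_two_locations_counts_twice(self):
        rec = pd.DataFrame({
            "location_id": ["A", "B"],
            "timestamp": pd.to_datetime(["2019-09-12 22:14:05"] * 2, utc=True),
        })
        assert len(ingest.to_positive_minutes(rec)) == 2

    def test_empty_input(self):
        out = ingest.to_positive_minutes(pd.DataFrame(columns=["location_id",
                                                               "timestamp"]))
        assert len(out) == 0

    def test_idempotent_and_bounded_by_record_count(self, small_scenario):
        minutes = ingest.to_positive_minutes(small_scenario.detections)
        assert len(minutes) <= len(small_scenario.detections)
        again = ingest.to_positive_minutes(minutes)
        pd.testing.assert_frame_equal(minutes, again)


class TestAssignNight:
    @pytest.mark.parametrize("ts, expected", [
        (datetime(2019, 9, 12, 23, 0, tzinfo=UTC), date(2019, 9, 12)),
        (datetime(2019, 9, 13, 3, 0, tzinfo=UTC), date(2019, 9, 12)),
        (datetime(2019, 9, 13, 16, 0, tzinfo=UTC), date(2019, 9, 13)),
    ])
    def test_boundary_examples(self, ts, expected):
        assert ingest.assign_night(ts) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(day=st.dates(min_value=date(2017, 1, 1), max_value=date(2021, 12, 31)),
           offset=st.integers(min_value=0, max_value=24 * 3600 - 1))
    def test_left_inverse_of_night_plus_offset(self, day, offset):
        ts = datetime(day.year, day.month, day.day, 16, tzinfo=UTC) \
            + timedelta(seconds=offset)
        assert ingest.assign_night(ts) == day


class TestReadWeather:
    HEADER = "station_id,timestamp,wind_dir,wind_speed,temperature,pressure,cloud,precip\n"

    def test_sentinel_codes_become_missing(self, tmp_path):
        p = _write(tmp_path, "wx.csv", self.HEADER +
                   "S1,2019-09-12T00:00:00Z,990,3.0,10.0,1013.0,9,0\n"
                   "S1,2019-09-12T01:00:00Z,0,0.0,10.0,1013.0,4,0\n"
                   "S1,2019-09-12T02:00:00Z,360,5.0,10.0,1013.0,4,0\n")
        out = ingest.read_weather(p)
        assert np.isnan(out.loc[0, "wind_dir"]) and np.isnan(out.loc[0, "cloud"])
        assert np.isnan(out.loc[1, "wind_dir"])          # calm: direction undefined
        assert out.loc[2, "wind_dir"] == 360.0           # north wind kept as-is
        assert out.loc[2, "wind_speed"] == 5.0

    def test_duplicate_station_hour_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "wx.csv", self.HEADER +
                   "S1,2019-09-12T00:00:00Z,90,3.0,10.0,1013.0,4,0\n"
                   "S1,2019-09-12T00:00:00Z,91,3.0,10.0,1013.0,4,0\n")
        with pytest.raises(ingest.IngestError, match="duplicate"):
            ingest.read_weather(p)

    def test_writer_round_trips_missing_values(self, tmp_path):
        wx = pd.DataFrame({
            "station_id": ["S1"] * 3,
            "timestamp": pd.date_range("2019-09-12", periods=3, freq="h", tz="UTC"),
            "wind_dir": [90.0, np.nan, 180.0],
            "wind_speed": [3.0, 4.0, np.nan],
            "temperature": [10.0, np.nan, 12.0],
            "pressure": [1013.0, 1014.0, np.nan],
            "cloud": [4.0, np.nan, 8.0],
            "precip": [0.0, 1.0, np.nan],
        })
        path = tmp_path / "wx.csv"
        ingest.write_weather(wx, path)
        back = ingest.read_weather(path)
        pd.testing.assert_frame_equal(back, wx, check_dtype=False)


def _station_table():
    return pd.DataFrame({"station_id": ["near", "mid", "far"],
                         "lon": [4.0, 4.5, 5.5], "lat": [52.0, 52.0, 52.0]})


def _weather_rows(station, hours, **values):
    n = len(hours)
    base = {"wind_dir": 90.0, "wind_speed": 3.0, "temperature": 10.0,
            "pressure": 1013.0, "cloud": 4.0, "precip": 0.0}
    base.update(values)
    return pd.DataFrame({"station_id": station, "timestamp": hours,
                         **{k: np.full(n, v, dtype=float) if np.isscalar(v) else v
                            for k, v in base.items()}})


class TestImputeWeather:
    HOURS = pd.date_range("2019-09-12 16:00", periods=3, freq="h", tz="UTC")

    def test_nearest_station_values_pass_through(self):
        wx = pd.concat([_weather_rows("near", self.HOURS, pressure=1013.2),
                        _weather_rows("mid", self.HOURS, pressure=999.0)],
                       ignore_index=True)
        out = ingest.impute_weather((4.0, 52.0), _station_table(), wx, self.HOURS)
        assert (out["pressure"] == 1013.2).all()

    def test_scalar_gap_filled_with_mean_of_two_closest(self):
        wx = pd.concat([
            _weather_rows("near", self.HOURS,
                          temperature=np.array([np.nan, 10.0, 10.0])),
            _weather_rows("mid", self.HOURS, temperature=10.0),
            _weather_rows("far", self.HOURS, temperature=12.0),
        ], ignore_index=True)
        out = ingest.impute_weather((4.0, 52.0), _station_table(), wx, self.HOURS)
        assert out["temperature"].iloc[0] == pytest.approx(11.0)
        assert (out["temperature"].iloc[1:] == 10.0).all()

    def test_wind_gap_filled_with_vector_mean(self):
        # nearest missing; neighbours blow from N (360) and E (90) at 2 m/s
        wx = pd.concat([
            _weather_rows("near", self.HOURS,
                          wind_dir=np.array([np.nan, 90.0, 90.0]),
                          wind_speed=np.array([np.nan, 3.0, 3.0])),
            _weather_rows("mid", self.HOURS, wind_dir=360.0, wind_speed=2.0),
            _weather_rows("far", self.HOURS, wind_dir=90.0, wind_speed=2.0),
        ], ignore_index=True)
        out = ingest.impute_weather((4.0, 52.0), _station_table(), wx, self.HOURS)
        assert out["wind_speed"].iloc[0] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert out["wind_dir"].iloc[0] == pytest.approx(45.0, abs=1e-9)

    def test_all_stations_missing_is_hard_error(self):
        wx = _weather_rows("near", self.HOURS,
                           pressure=np.array([np.nan, 1013.0, 1013.0]))
        with pytest.raises(ingest.IngestError, match="pressure"):
            ingest.impute_weather((4.0, 52.0), _station_table().iloc[:1], wx,
                                  self.HOURS)
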
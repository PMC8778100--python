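"""Weather reading, validation, and the synthetic regional generator."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cacaosim import (
    ARCHETYPES,
    WeatherCoverageError,
    WeatherSeries,
    accumulate_thermal_time,
    daily_mean_temperature,
    generate_synthetic_weather,
    read_power_weather,
)


@pytest.mark.parametrize(
    "tmax,tmin,expected", [(26, 26, 26.0), (30, 20, 25.0), (28.5, 21.5, 25.0)]
)
def test_daily_mean_temperature(tmax, tmin, expected):
    assert daily_mean_temperature(tmax, tmin) == expected


def test_daily_mean_temperature_rejects_inverted_extremes():
    with pytest.raises(ValueError, match="tmax"):
        daily_mean_temperature(20, 30)


class TestPowerReader:
    def _write(self, path, text):
        path.write_text(text)
        return path

    def test_parses_two_rows_and_mean_temperature(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "2019-07-12,30,20,15,0\n2019-07-13,28,22,12,3\n",
        )
        series = read_power_weather(f, "Apartado")
        assert len(series) == 2
        assert series.tmean.iloc[0] == 25.0
        assert series.frame["srad"].tolist() == [15.0, 12.0]

    def test_rows_out_of_order_are_sorted(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "2019-07-13,28,22,12,3\n2019-07-12,30,20,15,0\n",
        )
        series = read_power_weather(f, "x")
        assert list(series.frame.index.date) == [
            dt.date(2019, 7, 12),
            dt.date(2019, 7, 13),
        ]

    def test_power_header_block_and_yyyymmdd_dates(self, tmp_path):
        f = self._write(
            tmp_path / "p.csv",
            "-BEGIN HEADER-\nNASA/POWER export\n-END HEADER-\n"
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR,RH2M\n"
            "20190712,30,20,15,0,85\n20190713,28,22,12,3,88\n",
        )
        series = read_power_weather(f, "x")
        assert series.start == dt.date(2019, 7, 12)
        assert series.frame["rh"].iloc[1] == 88.0

    def test_year_doy_dates(self, tmp_path):
        f = self._write(
            tmp_path / "p.csv",
            "YEAR,DOY,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "2019,193,30,20,15,0\n",
        )
        assert read_power_weather(f, "x").start == dt.date(2019, 7, 12)

    def test_sentinel_becomes_missing_and_blocks_simulation(self, tmp_path):
        rows = "\n".join(
            f"2019-07-{d:02d},30,20,{-999 if d == 14 else 15},0"
            for d in range(12, 18)
        )
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n" + rows + "\n",
        )
        series = read_power_weather(f, "x")
        assert not (series.frame["srad"] <= -990).any()
        assert pd.Timestamp("2019-07-14") in series.missing_days
        assert not series.covers(
            dt.date(2019, 7, 12), dt.date(2019, 7, 17), ("srad",)
        )
        with pytest.raises(WeatherCoverageError):
            series.window(dt.date(2019, 7, 12), dt.date(2019, 7, 17))
        filled = series.fill_gaps(max_gap_days=3)
        assert filled.frame["srad"].notna().all()

    def test_long_gap_refuses_interpolation(self, tmp_path):
        rows = "\n".join(
            f"2019-07-{d:02d},30,20,{-999 if 13 <= d <= 17 else 15},0"
            for d in range(12, 20)
        )
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n" + rows + "\n",
        )
        with pytest.raises(WeatherCoverageError, match="gap"):
            read_power_weather(f, "x").fill_gaps(max_gap_days=3)

    def test_required_column_absent(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n2019-07-12,30,15,0\n",
        )
        with pytest.raises(ValueError, match="tmin"):
            read_power_weather(f, "x")

    def test_tmax_below_tmin_rejected(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "2019-07-12,20,30,15,0\n",
        )
        with pytest.raises(ValueError, match="tmax < tmin"):
            read_power_weather(f, "x")

    def test_unparsable_dates_rejected(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "not-a-date,30,20,15,0\n",
        )
        with pytest.raises(ValueError, match="date"):
            read_power_weather(f, "x")

    def test_duplicate_dates_rejected(self, tmp_path):
        f = self._write(
            tmp_path / "w.csv",
            "DATE,T2M_MAX,T2M_MIN,ALLSKY_SFC_SW_DWN,PRECTOTCORR\n"
            "2019-07-12,30,20,15,0\n2019-07-12,29,19,14,0\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_power_weather(f, "x")


def test_interior_calendar_gap_is_flagged(tmp_path):
    df = pd.DataFrame(
        {
            "date": ["2019-07-12", "2019-07-15"],
            "tmax": [30, 29],
            "tmin": [20, 21],
            "srad": [15, 14],
            "rain": [0, 0],
        }
    )
    series = WeatherSeries("x", df)
    assert len(series) == 4  # reindexed to the full span
    assert len(series.missing_days) == 2
    with pytest.raises(WeatherCoverageError):
        accumulate_thermal_time(series, dt.date(2019, 7, 12), horizon=3)


class TestSyntheticGenerator:
    def test_apartado_annual_mean_temperature(self):
        s = generate_synthetic_weather(
            ARCHETYPES["Apartado"], dt.date(2019, 1, 1), dt.date(2019, 12, 31), seed=1
        )
        assert abs(s.tmean.mean() - 26.0) < 0.5

    def test_caldas_annual_mean_temperature(self):
        s = generate_synthetic_weather(
            ARCHETYPES["Caldas"], dt.date(2019, 1, 1), dt.date(2019, 12, 31), seed=1
        )
        assert abs(s.tmean.mean() - 16.0) < 0.5

    def test_same_seed_is_bitwise_identical(self):
        a = ARCHETYPES["Santander"]
        s1 = generate_synthetic_weather(a, dt.date(2019, 1, 1), dt.date(2019, 6, 30), 7)
        s2 = generate_synthetic_weather(a, dt.date(2019, 1, 1), dt.date(2019, 6, 30), 7)
        pd.testing.assert_frame_equal(s1.frame, s2.frame)

    def test_different_seed_changes_series(self):
        a = ARCHETYPES["Santander"]
        s1 = generate_synthetic_weather(a, dt.date(2019, 1, 1), dt.date(2019, 6, 30), 7)
        s2 = generate_synthetic_weather(a, dt.date(2019, 1, 1), dt.date(2019, 6, 30), 8)
        assert not s1.frame["tmax"].equals(s2.frame["tmax"])

    def test_location_label_does_not_change_numbers(self):
        a = ARCHETYPES["Cali"]
        s1 = generate_synthetic_weather(a, dt.date(2019, 1, 1), dt.date(2019, 3, 1), 3)
        relabelled = dataclasses.replace(a, name="Elsewhere")
        s2 = generate_synthetic_weather(
            relabelled, dt.date(2019, 1, 1), dt.date(2019, 3, 1), 3
        )
        assert s2.location == "Elsewhere"
        pd.testing.assert_frame_equal(s1.frame, s2.frame)

    @pytest.mark.parametrize("region", sorted(ARCHETYPES))
    def test_physical_bounds_and_three_year_mean(self, region):
        a = ARCHETYPES[region]
        s = generate_synthetic_weather(
            a, dt.date(2018, 1, 1), dt.date(2020, 12, 31), seed=11
        )
        assert (s.frame["tmax"] >= s.frame["tmin"]).all()
        assert (s.frame["srad"] >= 0).all()
        assert (s.frame["rain"] >= 0).all()
        assert s.frame["rh"].between(0, 100).all()
        assert abs(s.tmean.mean() - a.mean_temp) < 0.3

    def test_rejects_inverted_date_range(self):
        with pytest.raises(ValueError, match="start"):
            generate_synthetic_weather(
                ARCHETYPES["Cali"], dt.date(2020, 1, 1), dt.date(2019, 1, 1), 1
            )


def test_csv_round_trip_is_exact(tmp_path):
    s = generate_synthetic_weather(
        ARCHETYPES["Arauca"], dt.date(2019, 1, 1), dt.date(2019, 12, 31), seed=5
    )
    path = s.to_csv(tmp_path / "arauca.csv")
    back = WeatherSeries.from_csv(path, "Arauca")
    pd.testing.assert_frame_equal(s.frame, back.frame)
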
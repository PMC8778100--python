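"""Daily weather series: NASA-POWER-style readers, validation, and a seeded
synthetic generator for the five Colombian cacao regions.

The simulator consumes one record per calendar day: maximum/minimum air
temperature (°C), incoming shortwave radiation SRAD (MJ m⁻² day⁻¹),
precipitation (mm), plus relative humidity, wind and dew point which are
carried for completeness but drive no equation.  Missing values are kept as
NaN and flagged, never silently filled: thermal time accumulated across an
unnoticed gap would corrupt every downstream prediction.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "POWER_COLUMN_MAP",
    "RegionArchetype",
    "ARCHETYPES",
    "WeatherSeries",
    "WeatherCoverageError",
    "daily_mean_temperature",
    "read_power_weather",
    "generate_synthetic_weather",
]

#: canonical column order of the normalised weather table (the ".WTH" role)
CANONICAL_COLUMNS = ["tmax", "tmin", "srad", "rain", "rh", "wind", "tdew"]

#: columns that must be present and numeric for any simulation to run
REQUIRED_COLUMNS = ["tmax", "tmin", "srad", "rain"]

#: NASA POWER export dialect -> canonical names
POWER_COLUMN_MAP: Mapping[str, str] = {
    "T2M_MAX": "tmax",
    "T2M_MIN": "tmin",
    "ALLSKY_SFC_SW_DWN": "srad",
    "PRECTOTCORR": "rain",
    "PRECTOT": "rain",
    "RH2M": "rh",
    "WS2M": "wind",
    "T2MDEW": "tdew",
}

#: POWER uses -999 for missing data
SENTINEL_THRESHOLD = -990.0


class WeatherCoverageError(ValueError):
    """Raised when a simulation window spans missing or absent weather days."""


def daily_mean_temperature(tmax: float, tmin: float) -> float:
    """Daily mean air temperature as (TMAX + TMIN) / 2.

    Raises ``ValueError`` if ``tmax < tmin``.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    return (tmax + tmin) / 2.0


@dataclass(frozen=True)
class RegionArchetype:
    """Statistical description of one region's climate for the generator.

    Temperatures in °C, radiation in MJ m⁻² day⁻¹.  ``temp_peak_doy`` and
    ``srad_peak_doy`` place the annual sinusoid maximum on a day of year.
    ``bimodal_rain_peaks`` lists (first_month, last_month) wet-season spans.
    """

    name: str
    mean_temp: float
    temp_seasonal_amplitude: float
    temp_daily_noise_sd: float
    mean_srad: float
    srad_amplitude: float
    srad_noise_sd: float = 2.0
    diurnal_range: float = 8.0
    temp_peak_doy: float = 75.0
    srad_peak_doy: float = 45.0
    bimodal_rain_peaks: tuple[tuple[int, int], ...] = ((2, 4), (10, 11))
    rh_mean: float = 85.0
    wind_mean: float = 1.5
    rain_wet_prob: float = 0.60
    rain_dry_prob: float = 0.20
    rain_wet_mm: float = 14.0
    rain_dry_mm: float = 5.0

    def __post_init__(self) -> None:
        if not (14.0 <= self.mean_temp <= 30.0):
            raise ValueError(f"mean_temp {self.mean_temp} outside [14, 30] °C")
        if not (3.0 <= self.mean_srad <= 22.0):
            raise ValueError(f"mean_srad {self.mean_srad} outside [3, 22]")


# Mean temperatures are back-derived from each region's 180-day thermal-time
# requirement (Tsum/180 + Tb); radiation follows the qualitative regional
# contrast: the cool highlands (Santander, Caldas) receive the most shortwave
# (peaks above 20 MJ m-2 day-1), Cali and Arauca the least.
ARCHETYPES: Mapping[str, RegionArchetype] = {
    "Apartado": RegionArchetype(
        name="Apartado", mean_temp=26.1, temp_seasonal_amplitude=0.7,
        temp_daily_noise_sd=0.7, mean_srad=14.5, srad_amplitude=2.0,
    ),
    "Arauca": RegionArchetype(
        name="Arauca", mean_temp=25.4, temp_seasonal_amplitude=1.8,
        temp_daily_noise_sd=0.9, mean_srad=12.5, srad_amplitude=2.0,
        temp_peak_doy=75.0,  # hotter months in the first half of the year
    ),
    "Santander": RegionArchetype(
        name="Santander", mean_temp=21.2, temp_seasonal_amplitude=1.2,
        temp_daily_noise_sd=0.8, mean_srad=17.5, srad_amplitude=3.5,
        srad_noise_sd=2.5,
    ),
    "Cali": RegionArchetype(
        name="Cali", mean_temp=20.6, temp_seasonal_amplitude=0.8,
        temp_daily_noise_sd=0.8, mean_srad=12.0, srad_amplitude=2.0,
    ),
    "Caldas": RegionArchetype(
        name="Caldas", mean_temp=16.4, temp_seasonal_amplitude=0.6,
        temp_daily_noise_sd=0.7, mean_srad=17.0, srad_amplitude=3.5,
        srad_noise_sd=2.5,
    ),
}


def _as_timestamp(d: dt.date | str | pd.Timestamp) -> pd.Timestamp:
    return pd.Timestamp(d).normalize()


class WeatherSeries:
    """A validated, date-indexed daily weather table for one location.

    The underlying frame is reindexed onto the full daily range between the
    first and last record, so missing days appear as NaN rows and are
    reported by :attr:`missing_days` rather than silently absent.
    """

    def __init__(self, location: str, frame: pd.DataFrame):
        df = frame.copy()
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"])
            df = df.set_index("date")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("weather frame needs a 'date' column or DatetimeIndex")
        df.index = df.index.normalize()
        df.index.name = "date"
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0].date()
            raise ValueError(f"duplicate weather date: {dup}")
        df = df.sort_index()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"required weather column missing: {col!r}")
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        df = df[CANONICAL_COLUMNS]
        bad = df.dropna(subset=["tmax", "tmin"])
        bad = bad[bad["tmax"] < bad["tmin"]]
        if len(bad):
            d = bad.index[0].date()
            raise ValueError(
                f"tmax < tmin on {d}: {bad['tmax'].iloc[0]} < {bad['tmin'].iloc[0]}"
            )
        if (df["srad"].dropna() < 0).any() or (df["rain"].dropna() < 0).any():
            raise ValueError("negative srad or rain in weather series")
        if len(df):
            full = pd.date_range(df.index[0], df.index[-1], freq="D")
            df = df.reindex(full)
            df.index.name = "date"
        self.location = str(location)
        self.frame = df

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if len(self) == 0:
            return f"WeatherSeries({self.location!r}, empty)"
        return (
            f"WeatherSeries({self.location!r}, {self.frame.index[0].date()} .. "
            f"{self.frame.index[-1].date()}, n={len(self)}, "
            f"missing={len(self.missing_days)})"
        )

    @property
    def start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.frame.index[-1].date()

    @property
    def tmean(self) -> pd.Series:
        """Daily mean temperature, (tmax + tmin)/2, NaN where either is missing."""
        return (self.frame["tmax"] + self.frame["tmin"]) / 2.0

    @property
    def missing_days(self) -> pd.DatetimeIndex:
        """Days where any required driver (tmax/tmin/srad/rain) is missing."""
        mask = self.frame[REQUIRED_COLUMNS].isna().any(axis=1)
        return self.frame.index[mask]

    def with_location(self, location: str) -> "WeatherSeries":
        out = WeatherSeries.__new__(WeatherSeries)
        out.location = str(location)
        out.frame = self.frame
        return out

    # -- coverage ----------------------------------------------------------
    def covers(
        self,
        start: dt.date,
        end: dt.date,
        columns: Sequence[str] = ("tmax", "tmin"),
    ) -> bool:
        """True if every day in [start, end] is present with non-NaN columns."""
        s, e = _as_timestamp(start), _as_timestamp(end)
        if len(self) == 0 or s < self.frame.index[0] or e > self.frame.index[-1]:
            return False
        window = self.frame.loc[s:e, list(columns)]
        return not window.isna().any(axis=None)

    def contiguous_days_from(
        self, start: dt.date, columns: Sequence[str] = ("tmax", "tmin")
    ) -> int:
        """Number of consecutive valid days starting at ``start`` (inclusive)."""
        s = _as_timestamp(start)
        if len(self) == 0 or s < self.frame.index[0] or s > self.frame.index[-1]:
            return 0
        valid = ~self.frame.loc[s:, list(columns)].isna().any(axis=1)
        arr = valid.to_numpy()
        if not arr[0]:
            return 0
        gaps = np.flatnonzero(~arr)
        return int(gaps[0]) if len(gaps) else int(len(arr))

    def window(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Inclusive daily slice; raises if any required driver is missing."""
        s, e = _as_timestamp(start), _as_timestamp(end)
        if not self.covers(start, end, REQUIRED_COLUMNS):
            raise WeatherCoverageError(
                f"{self.location}: weather does not cover "
                f"{s.date()} .. {e.date()} without gaps"
            )
        return self.frame.loc[s:e]

    # -- gap handling ------------------------------------------------------
    def fill_gaps(self, max_gap_days: int = 3) -> "WeatherSeries":
        """Linearly interpolate interior gaps of at most ``max_gap_days``.

        Explicit opt-in: nothing ever interpolates implicitly.  Raises
        :class:`WeatherCoverageError` if any gap exceeds the limit.
        """
        df = self.frame.copy()
        mask = df[REQUIRED_COLUMNS].isna().any(axis=1).to_numpy()
        # measure run lengths of missing days
        run = 0
        for m in mask:
            run = run + 1 if m else 0
            if run > max_gap_days:
                raise WeatherCoverageError(
                    f"{self.location}: gap longer than {max_gap_days} days"
                )
        df = df.interpolate(method="time", limit_area="inside")
        return WeatherSeries(self.location, df.reset_index())

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write the normalised weather table (ISO dates, canonical columns)."""
        path = Path(path)
        out = self.frame.reset_index()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, location: str | None = None) -> "WeatherSeries":
        """Read a table previously written by :meth:`to_csv`."""
        path = Path(path)
        df = pd.read_csv(path)
        return cls(location or path.stem, df)


def read_power_weather(
    path: str | Path,
    location: str,
    column_map: Mapping[str, str] | None = None,
) -> WeatherSeries:
    """Read a NASA-POWER-export-style delimited file into a WeatherSeries.

    Accepts either the raw POWER Data Access Viewer CSV (optional commented
    header terminated by ``-END HEADER-``, columns like ``T2M_MAX`` and a
    ``YYYYMMDD`` date or ``YEAR``/``DOY`` pair) or any delimited table whose
    columns can be mapped onto the canonical names via ``column_map``.
    ``-999`` sentinels become missing values; they are never used as numbers.
    """
    path = Path(path)
    skiprows = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if "-END HEADER-" in line:
                skiprows = i + 1
                break
            if i > 200:
                break
    df = pd.read_csv(path, skiprows=skiprows)
    df.columns = [c.strip() for c in df.columns]

    mapping = dict(POWER_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    # accept canonical and upper-case canonical names as-is
    for c in CANONICAL_COLUMNS:
        mapping.setdefault(c.upper(), c)
        mapping.setdefault(c, c)
    df = df.rename(columns={c: mapping[c] for c in df.columns if c in mapping})

    df = _attach_dates(df)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: required column(s) absent: {missing}")
    keep = ["date"] + [c for c in CANONICAL_COLUMNS if c in df.columns]
    df = df[keep]
    num = df.columns.drop("date")
    df[num] = df[num].apply(pd.to_numeric, errors="coerce")
    df[num] = df[num].mask(df[num] <= SENTINEL_THRESHOLD)
    return WeatherSeries(location, df)


def _attach_dates(df: pd.DataFrame) -> pd.DataFrame:
    cols = {c.upper(): c for c in df.columns}
    if "date" in df.columns or "DATE" in cols:
        col = df.columns[[c.upper() == "DATE" for c in df.columns]][0]
        raw = df[col]
        try:
            if pd.api.types.is_integer_dtype(raw) or (
                raw.astype(str).str.fullmatch(r"\d{8}").all()
            ):
                dates = pd.to_datetime(raw.astype(str), format="%Y%m%d")
            else:
                dates = pd.to_datetime(raw)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparsable dates in column {col!r}: {exc}") from exc
        return df.assign(date=dates)
    if "YEAR" in cols and "DOY" in cols:
        dates = pd.to_datetime(
            df[cols["YEAR"]].astype(int).astype(str), format="%Y"
        ) + pd.to_timedelta(df[cols["DOY"]].astype(int) - 1, unit="D")
        return df.assign(date=dates)
    if "YEAR" in cols and "MO" in cols and "DY" in cols:
        dates = pd.to_datetime(
            dict(
                year=df[cols["YEAR"]].astype(int),
                month=df[cols["MO"]].astype(int),
                day=df[cols["DY"]].astype(int),
            )
        )
        return df.assign(date=dates)
    raise ValueError("no recognisable date column (DATE / YYYYMMDD / YEAR+DOY)")


def generate_synthetic_weather(
    archetype: RegionArchetype,
    start: dt.date,
    end: dt.date,
    seed: int,
    location: str | None = None,
) -> WeatherSeries:
    """Generate a seeded daily weather series emulating one regional climate.

    Daily mean temperature and shortwave radiation follow an annual cosine
    (peaking at the archetype's peak day-of-year) plus Gaussian noise; tmax
    and tmin straddle the mean by a noisy diurnal range; rainfall intensity
    is bimodal across the two Colombian wet seasons; humidity stays high.
    The same ``(archetype, start, end, seed)`` always yields the identical
    series; the location label never enters the number stream.
    """
    if start >= end:
        raise ValueError("start must precede end")
    rng = np.random.default_rng(seed)
    index = pd.date_range(_as_timestamp(start), _as_timestamp(end), freq="D")
    n = len(index)
    doy = index.dayofyear.to_numpy(dtype=float)

    season = np.cos(2 * np.pi * (doy - archetype.temp_peak_doy) / 365.25)
    tmean = (
        archetype.mean_temp
        + archetype.temp_seasonal_amplitude * season
        + rng.normal(0.0, archetype.temp_daily_noise_sd, n)
    )
    diurnal = np.maximum(archetype.diurnal_range + rng.normal(0.0, 1.0, n), 1.0)
    tmax = tmean + diurnal / 2.0
    tmin = tmean - diurnal / 2.0

    srad_season = np.cos(2 * np.pi * (doy - archetype.srad_peak_doy) / 365.25)
    srad = np.clip(
        archetype.mean_srad
        + archetype.srad_amplitude * srad_season
        + rng.normal(0.0, archetype.srad_noise_sd, n),
        0.3,
        None,
    )

    month = index.month.to_numpy()
    wet = np.zeros(n, dtype=bool)
    for lo, hi in archetype.bimodal_rain_peaks:
        wet |= (month >= lo) & (month <= hi)
    p_rain = np.where(wet, archetype.rain_wet_prob, archetype.rain_dry_prob)
    rainy = rng.random(n) < p_rain
    amounts = rng.gamma(
        1.2, np.where(wet, archetype.rain_wet_mm, archetype.rain_dry_mm) / 1.2
    )
    rain = np.where(rainy, amounts, 0.0)

    rh = np.clip(archetype.rh_mean + rng.normal(0.0, 3.0, n), 55.0, 100.0)
    wind = rng.gamma(2.0, archetype.wind_mean / 2.0, n)
    tdew = tmin - rng.uniform(0.0, 2.0, n)

    df = pd.DataFrame(
        {
            "date": index,
            "tmax": tmax,
            "tmin": tmin,
            "srad": srad,
            "rain": rain,
            "rh": rh,
            "wind": wind,
            "tdew": tdew,
        }
    )
    return WeatherSeries(location or archetype.name, df)
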
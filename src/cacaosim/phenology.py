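"""Thermal-time phenology: degree-day accumulation from flowering date,
regional Tsum characterisation, and harvest-day prediction.

Cacao pods are harvested by tradition at a fixed 180 days after flowering
(DAF) regardless of climate.  The model instead tracks thermal time — the
cumulative daily excess of mean temperature over a base temperature of
10 °C (the minimum for cacao pod growth) — and declares a pod mature on the
first day the accumulation reaches the regional requirement Tsum.  Tsum
itself is characterised as the mean 180-DAF accumulation over observed
flowering dates in each region.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .weather import WeatherCoverageError, WeatherSeries

__all__ = [
    "ThermalTimeParams",
    "FloweringSample",
    "ThermalTimeTrace",
    "TsumCharacterisation",
    "HarvestPrediction",
    "thermal_increment",
    "accumulate_thermal_time",
    "characterize_tsum",
    "predict_harvest_day",
    "monthly_harvest_table",
]

HARVEST_OFFSET_DAYS = 180  # the traditional calendar harvest, FD + 180 d


@dataclass(frozen=True)
class ThermalTimeParams:
    """Base temperature Tb (°C) below which pods accrue no development."""

    tbase: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tbase <= 15.0):
            raise ValueError(f"tbase {self.tbase} outside [0, 15] °C")


@dataclass(frozen=True)
class FloweringSample:
    """One field record: a flowering date with its observed outcome.

    ``observed_harvest_date``, when present, must sit exactly 180 days after
    flowering (the farmers' calendar rule under which yields were recorded).
    Yield is dry beans in kg ha⁻¹ yr⁻¹.
    """

    region: str
    flowering_date: dt.date
    observed_harvest_date: dt.date | None = None
    observed_yield: float | None = None
    plant_density: float | None = None
    tree_age: float | None = None
    pods_per_ha: float | None = None

    def __post_init__(self) -> None:
        if self.observed_harvest_date is not None:
            delta = (self.observed_harvest_date - self.flowering_date).days
            if delta != HARVEST_OFFSET_DAYS:
                raise ValueError(
                    f"observed harvest must be FD + {HARVEST_OFFSET_DAYS} d, "
                    f"got FD + {delta} d"
                )


@dataclass(frozen=True)
class ThermalTimeTrace:
    """Cumulative thermal time indexed by DAF; ``daily_tt[0] == 0`` at FD."""

    flowering_date: dt.date
    daily_tt: np.ndarray

    def __post_init__(self) -> None:
        tt = np.asarray(self.daily_tt, dtype=float)
        object.__setattr__(self, "daily_tt", tt)
        if tt[0] != 0.0:
            raise ValueError("thermal time must start at 0 on the flowering date")
        if np.any(np.diff(tt) < 0):
            raise ValueError("thermal time must be non-decreasing")

    def __len__(self) -> int:
        return len(self.daily_tt)


@dataclass(frozen=True)
class HarvestPrediction:
    """First DAF at which accumulated thermal time reaches Tsum.

    ``reached`` is False when the crop-cycle cap expired first, in which case
    ``daf`` equals the cap.
    """

    flowering_date: dt.date
    daf: int
    reached: bool
    tt_at_harvest: float

    @property
    def harvest_date(self) -> dt.date:
        return self.flowering_date + dt.timedelta(days=int(self.daf))


@dataclass(frozen=True)
class TsumCharacterisation:
    """Regional thermal-time requirement with its per-sample distribution."""

    region: str
    tsum: float
    per_sample: np.ndarray
    flowering_dates: tuple[dt.date, ...]
    horizon: int = HARVEST_OFFSET_DAYS
    statistic: str = "mean"


def thermal_increment(tmean: float, params: ThermalTimeParams = ThermalTimeParams()):
    """Daily degree-day increment: max(tmean − Tb, 0).  Accepts arrays."""
    return np.maximum(np.asarray(tmean, dtype=float) - params.tbase, 0.0)[()]


def accumulate_thermal_time(
    series: WeatherSeries,
    fd: dt.date,
    horizon: int = HARVEST_OFFSET_DAYS,
    params: ThermalTimeParams = ThermalTimeParams(),
) -> ThermalTimeTrace:
    """Cumulative thermal time over DAF 0..horizon starting at flowering.

    Day 0 (the flowering date itself) contributes nothing; the increment for
    DAF d uses the weather of calendar day fd + d.  Requires gap-free
    temperature coverage of [fd, fd + horizon].
    """
    fd = pd.Timestamp(fd).date()
    end = fd + dt.timedelta(days=int(horizon))
    if not series.covers(fd, end, ("tmax", "tmin")):
        raise WeatherCoverageError(
            f"{series.location}: no gap-free temperature coverage "
            f"{fd} .. {end} (flowering {fd}, horizon {horizon} d)"
        )
    window = series.frame.loc[pd.Timestamp(fd): pd.Timestamp(end)]
    tmean = ((window["tmax"] + window["tmin"]) / 2.0).to_numpy()[1:]
    inc = np.maximum(tmean - params.tbase, 0.0)
    daily_tt = np.concatenate(([0.0], np.cumsum(inc)))
    return ThermalTimeTrace(fd, daily_tt)


def characterize_tsum(
    series: WeatherSeries,
    samples: Sequence[FloweringSample | dt.date],
    horizon: int = HARVEST_OFFSET_DAYS,
    params: ThermalTimeParams = ThermalTimeParams(),
    statistic: str = "mean",
) -> TsumCharacterisation:
    """Regional Tsum: the 180-DAF thermal-time accumulation aggregated over
    flowering dates.

    ``statistic`` is "mean" (default) or "median"; the full per-sample
    distribution is returned either way for box-plot style summaries.
    """
    fds = [
        s.flowering_date if isinstance(s, FloweringSample) else pd.Timestamp(s).date()
        for s in samples
    ]
    if not fds:
        raise ValueError("at least one flowering date is required")
    per = np.array(
        [
            accumulate_thermal_time(series, fd, horizon, params).daily_tt[horizon]
            for fd in fds
        ]
    )
    if statistic == "mean":
        tsum = float(np.mean(per))
    elif statistic == "median":
        tsum = float(np.median(per))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return TsumCharacterisation(
        region=series.location,
        tsum=tsum,
        per_sample=per,
        flowering_dates=tuple(fds),
        horizon=horizon,
        statistic=statistic,
    )


def _tt_until(
    series: WeatherSeries,
    fd: dt.date,
    tsum: float,
    cap: int,
    params: ThermalTimeParams,
) -> tuple[np.ndarray, int, bool]:
    """Thermal-time trace up to the Tsum crossing or the cycle cap.

    Accumulates only as far as contiguous weather coverage allows; it is an
    error only when the requirement is not met *and* coverage ends before
    the cap, so a series that ends shortly after maturity still works.
    """
    fd = pd.Timestamp(fd).date()
    if tsum <= 0:
        raise ValueError("tsum must be positive")
    avail = series.contiguous_days_from(fd, ("tmax", "tmin")) - 1
    if avail < 0:
        raise WeatherCoverageError(f"{series.location}: no weather at {fd}")
    horizon = min(int(cap), avail)
    trace = accumulate_thermal_time(series, fd, horizon, params)
    tt = trace.daily_tt
    hit = np.flatnonzero(tt >= tsum)
    if len(hit):
        d = int(hit[0])
        return tt, d, True
    if horizon < cap:
        raise WeatherCoverageError(
            f"{series.location}: Tsum {tsum:.0f} not reached by DAF {horizon} "
            f"and weather coverage ends before the {cap}-day cap (flowering {fd})"
        )
    return tt, int(cap), False


def predict_harvest_day(
    series: WeatherSeries,
    fd: dt.date,
    tsum: float,
    params: ThermalTimeParams = ThermalTimeParams(),
    cap: int = 200,
) -> HarvestPrediction:
    """Smallest DAF whose cumulative thermal time reaches ``tsum``.

    Under constant mean temperature T > Tb this is ceil(tsum / (T − Tb)).
    If the requirement is not met by ``cap`` days (the crop-cycle limit),
    the cap is returned with ``reached=False``.
    """
    fd = pd.Timestamp(fd).date()
    tt, daf, reached = _tt_until(series, fd, tsum, cap, params)
    return HarvestPrediction(
        flowering_date=fd,
        daf=daf,
        reached=reached,
        tt_at_harvest=float(tt[min(daf, len(tt) - 1)]),
    )


def monthly_harvest_table(
    series: WeatherSeries,
    samples: Sequence[FloweringSample | dt.date],
    tsum: float,
    params: ThermalTimeParams = ThermalTimeParams(),
    cap: int = 200,
) -> pd.Series:
    """Mean predicted harvest DAF grouped by calendar month of flowering.

    Returns a Series indexed by month number (1–12); months without a
    flowering date are absent.
    """
    fds = [
        s.flowering_date if isinstance(s, FloweringSample) else pd.Timestamp(s).date()
        for s in samples
    ]
    rows = [
        (fd.month, predict_harvest_day(series, fd, tsum, params, cap).daf)
        for fd in fds
    ]
    df = pd.DataFrame(rows, columns=["month", "daf"])
    out = df.groupby("month")["daf"].mean()
    out.name = "mean_predicted_daf"
    return out
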
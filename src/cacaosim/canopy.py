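"""Canopy light interception and radiation-use-efficiency biomass simulation.

The daily growth engine follows the SIMPLE generic crop model family,
re-parameterised for a perennial cacao pod cycle that starts at flowering
rather than sowing:

    rate_d = SRAD_d · fSolar(tt_d) · RUE · f(CO2) · f(T) · min(f_heat, f_water) · 10

with SRAD in MJ m⁻² day⁻¹ and RUE in g MJ⁻¹, so the product is
g m⁻² day⁻¹ and the factor 10 converts to kg ha⁻¹ day⁻¹.  fSolar is the
point-wise minimum of a logistic canopy-growth curve (half-saturation I50A
degree-days after flowering) and a logistic senescence curve anchored
I50B degree-days before the regional thermal-time requirement Tsum.  The
cycle stops on the first day cumulative thermal time reaches Tsum (or at
the 200-day crop-cycle cap) and yield is the harvest-index fraction of
accumulated above-ground biomass.

Heat and water stress machinery is present but neutral at the shipped
parameters (S_water = 0; Colombian tmax stays below the 35 °C heat onset).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .phenology import ThermalTimeParams, _tt_until
from .weather import WeatherSeries

__all__ = [
    "SpeciesCultivarParams",
    "RegionParams",
    "REGION_PARAMS",
    "SimulationTrace",
    "fsolar",
    "ftemp",
    "fco2",
    "fheat",
    "fwater",
    "daily_biomass_rate",
    "simulate_cycle",
]

#: g m⁻² day⁻¹ → kg ha⁻¹ day⁻¹
G_M2_TO_KG_HA = 10.0

#: reference CO2 for the response function, ppm
CO2_REFERENCE = 350.0
CO2_SATURATION = 700.0

#: steepness of both fSolar logistics per degree-day (SIMPLE convention)
FSOLAR_STEEPNESS = 0.01


@dataclass(frozen=True)
class SpeciesCultivarParams:
    """Physiological parameters shared by the ICS95 and CCN51 cultivars.

    Temperatures in °C; ``i50a``/``i50b`` in degree-days; ``s_co2`` is the
    fractional RUE gain per 100 ppm CO2 above 350; ``hi`` the harvest
    index; ``cycle_cap`` the maximum simulated cycle length in days.
    ``initial_fsolar`` is recorded from the input layout but the logistic
    governs day-0 interception (~0.001); it is not used as a floor.
    """

    tbase: float = 10.0
    topt: float = 26.0
    maxt: float = 35.0
    extremet: float = 40.0
    s_co2: float = 0.09
    s_water: float = 0.0
    i50a: float = 680.0
    i50b: float = 680.0
    hi: float = 0.3
    fsolar_max: float = 0.94
    initial_fsolar: float = 0.01
    cycle_cap: int = 200

    def __post_init__(self) -> None:
        if not (self.tbase < self.topt < self.maxt < self.extremet):
            raise ValueError(
                "temperature cardinals must satisfy tbase < topt < maxt < extremet"
            )
        if not (0.0 < self.hi < 1.0):
            raise ValueError(f"harvest index {self.hi} outside (0, 1)")
        if not (0.0 < self.fsolar_max <= 1.0):
            raise ValueError(f"fsolar_max {self.fsolar_max} outside (0, 1]")
        if self.i50a <= 0 or self.i50b <= 0:
            raise ValueError("i50a and i50b must be positive")
        if self.s_water < 0 or self.s_co2 < 0:
            raise ValueError("s_water and s_co2 must be non-negative")
        if self.cycle_cap <= 0:
            raise ValueError("cycle_cap must be positive")


@dataclass(frozen=True)
class RegionParams:
    """Region-calibrated triple: Tsum (°C·day), RUE (g MJ⁻¹, above-ground,
    respiration-free) and the observed annual yield (kg ha⁻¹ yr⁻¹)."""

    region: str
    tsum: float
    rue: float
    observed_yield: float | None = None

    def __post_init__(self) -> None:
        if self.tsum <= 0:
            raise ValueError("tsum must be positive")
        if not (0.4 <= self.rue <= 0.9):
            raise ValueError(f"rue {self.rue} outside the calibrated band [0.4, 0.9]")


#: regional calibration shipped with the model
REGION_PARAMS: Mapping[str, RegionParams] = {
    "Apartado": RegionParams("Apartado", tsum=2906.0, rue=0.6, observed_yield=3378.0),
    "Arauca": RegionParams("Arauca", tsum=2764.0, rue=0.7, observed_yield=3981.0),
    "Santander": RegionParams("Santander", tsum=2016.0, rue=0.6, observed_yield=2687.0),
    "Cali": RegionParams("Cali", tsum=1912.0, rue=0.5, observed_yield=1900.0),
    "Caldas": RegionParams("Caldas", tsum=1192.0, rue=0.6, observed_yield=740.0),
}


def fsolar(tt, p: SpeciesCultivarParams, tsum: float):
    """Fraction of solar radiation intercepted at thermal time ``tt``.

    fsolar_max · min(growth, senescence) where both branches are logistics
    with steepness 0.01 per degree-day.  The curve peaks at
    tt* = (i50a + tsum − i50b) / 2.  Accepts scalars or arrays.
    """
    tt = np.asarray(tt, dtype=float)
    growth = 1.0 / (1.0 + np.exp(-FSOLAR_STEEPNESS * (tt - p.i50a)))
    senescence = 1.0 / (1.0 + np.exp(FSOLAR_STEEPNESS * (tt - (tsum - p.i50b))))
    return (p.fsolar_max * np.minimum(growth, senescence))[()]


def fsolar_peak(p: SpeciesCultivarParams, tsum: float) -> float:
    """Closed-form maximum of the fSolar curve over thermal time."""
    tt_star = (p.i50a + tsum - p.i50b) / 2.0
    return float(p.fsolar_max / (1.0 + np.exp(-FSOLAR_STEEPNESS * (tt_star - p.i50a))))


def ftemp(tmean, p: SpeciesCultivarParams):
    """Temperature response: 0 below Tbase, linear ramp to 1 at Topt."""
    tmean = np.asarray(tmean, dtype=float)
    ramp = (tmean - p.tbase) / (p.topt - p.tbase)
    return np.clip(ramp, 0.0, 1.0)[()]


def fco2(co2: float, p: SpeciesCultivarParams) -> float:
    """CO2 fertilisation multiplier: 1 at 350 ppm, +s_co2 per 100 ppm,
    saturating at 700 ppm."""
    if co2 <= 0:
        raise ValueError("co2 must be positive")
    clipped = min(max(co2, CO2_REFERENCE), CO2_SATURATION)
    return 1.0 + p.s_co2 * (clipped - CO2_REFERENCE) / 100.0


def fheat(tmax, p: SpeciesCultivarParams):
    """Heat stress: 1 up to MaxT, declining linearly to 0 at ExtremeT."""
    tmax = np.asarray(tmax, dtype=float)
    decline = (p.extremet - tmax) / (p.extremet - p.maxt)
    return np.clip(decline, 0.0, 1.0)[()]


def fwater(arid, p: SpeciesCultivarParams):
    """Drought stress 1 − s_water·ARID; identically 1 with s_water = 0."""
    arid = np.asarray(arid, dtype=float)
    if np.any(arid < 0) or np.any(arid > 1):
        raise ValueError("ARID index must lie in [0, 1]")
    return (1.0 - p.s_water * arid)[()]


def daily_biomass_rate(srad, fsolar_value, rue, fco2_value, ftemp_value,
                       fheat_value=1.0, fwater_value=1.0):
    """Daily above-ground growth in kg ha⁻¹ day⁻¹ (×10 unit conversion)."""
    return (
        np.asarray(srad, dtype=float)
        * fsolar_value
        * rue
        * fco2_value
        * ftemp_value
        * np.minimum(fheat_value, fwater_value)
        * G_M2_TO_KG_HA
    )[()]


@dataclass(frozen=True)
class SimulationTrace:
    """Daily state of one simulated pod cycle plus its harvest summary.

    Arrays are indexed by DAF 0..predicted_harvest_daf; day 0 carries zero
    thermal time and zero growth.  ``yield_kg_ha`` equals
    ``hi × cumulative_biomass[-1]`` exactly.
    """

    region: str
    flowering_date: dt.date
    daf: np.ndarray
    tt: np.ndarray
    fsolar: np.ndarray
    biomass_rate: np.ndarray
    cumulative_biomass: np.ndarray
    predicted_harvest_daf: int
    reached: bool
    yield_kg_ha: float

    @property
    def harvest_date(self) -> dt.date:
        return self.flowering_date + dt.timedelta(days=int(self.predicted_harvest_daf))

    @property
    def total_biomass(self) -> float:
        return float(self.cumulative_biomass[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-day table (one row per DAF) for CSV export."""
        dates = pd.date_range(pd.Timestamp(self.flowering_date), periods=len(self.daf))
        return pd.DataFrame(
            {
                "date": dates.strftime("%Y-%m-%d"),
                "daf": self.daf,
                "tt": self.tt,
                "fsolar": self.fsolar,
                "biomass_rate": self.biomass_rate,
                "cumulative_biomass": self.cumulative_biomass,
            }
        )


def simulate_cycle(
    series: WeatherSeries,
    fd: dt.date,
    region: RegionParams,
    p: SpeciesCultivarParams = SpeciesCultivarParams(),
    co2: float = 400.0,
    arid: float = 0.0,
) -> SimulationTrace:
    """Simulate one pod cycle from flowering to predicted harvest.

    Runs the daily loop — thermal time, fSolar, growth rate, cumulative
    biomass — stopping on the first day thermal time reaches the regional
    Tsum, or at the crop-cycle cap with ``reached=False``.  Yield is the
    harvest-index share of the biomass accumulated by the stop day.
    """
    fd = pd.Timestamp(fd).date()
    tt_params = ThermalTimeParams(tbase=p.tbase)
    tt_full, harvest_daf, reached = _tt_until(
        series, fd, region.tsum, p.cycle_cap, tt_params
    )
    d = int(harvest_daf)
    tt = tt_full[: d + 1]

    end = fd + dt.timedelta(days=d)
    window = series.window(fd, end)  # validates srad/rain coverage too
    tmean = ((window["tmax"] + window["tmin"]) / 2.0).to_numpy()
    tmax = window["tmax"].to_numpy()
    srad = window["srad"].to_numpy()

    fs = np.asarray(fsolar(tt, p, region.tsum))
    rate = np.asarray(
        daily_biomass_rate(
            srad,
            fs,
            region.rue,
            fco2(co2, p),
            ftemp(tmean, p),
            fheat(tmax, p),
            fwater(arid, p),
        )
    )
    rate[0] = 0.0  # flowering day contributes neither thermal time nor growth
    cumulative = np.cumsum(rate)
    yield_kg_ha = p.hi * float(cumulative[-1])
    return SimulationTrace(
        region=region.region,
        flowering_date=fd,
        daf=np.arange(d + 1),
        tt=tt,
        fsolar=fs,
        biomass_rate=rate,
        cumulative_biomass=cumulative,
        predicted_harvest_daf=d,
        reached=reached,
        yield_kg_ha=yield_kg_ha,
    )
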
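"""Seven-file CSV configuration bundle and offline fixture generation.

The model is driven by seven small CSV files in one directory, mirroring
the input layout of the original calibration:

    soil.csv         inert soil metadata (no water balance is computed)
    treatment.csv    weather file pattern, CO2 ppm, crop-cycle cap; the
                     treatment "sowing date" is the flowering date
    observation.csv  LAI, observed fSolar, per-plant biomass, harvest index
    cultivar.csv     I50A / I50B per cultivar (ICS95, CCN51)
    species.csv      temperature cardinals, CO2 and water sensitivities
    regions.csv      per-region Tsum, RUE and observed annual yield
    samples.csv      flowering-date field samples

``make_fixtures`` writes a complete synthetic study — weather, samples and
the seven-file bundle for all five regions — so every command runs
offline and reproducibly from a single seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .canopy import REGION_PARAMS, RegionParams, SpeciesCultivarParams
from .phenology import FloweringSample
from .weather import ARCHETYPES, WeatherSeries, generate_synthetic_weather

__all__ = [
    "ConfigError",
    "ConfigBundle",
    "CONFIG_FILES",
    "load_config",
    "write_default_config",
    "load_weather_for_region",
    "make_fixtures",
    "reconstructed_flowering_dates",
    "FD_FIRST",
    "FD_LAST",
    "SAMPLES_PER_REGION",
]

CONFIG_FILES = (
    "soil.csv",
    "treatment.csv",
    "observation.csv",
    "cultivar.csv",
    "species.csv",
    "regions.csv",
    "samples.csv",
)

#: flowering-date window of the field campaign
FD_FIRST = dt.date(2019, 7, 12)
FD_LAST = dt.date(2020, 6, 23)
SAMPLES_PER_REGION = 23

#: fixture weather span: starts with the study period and extends past the
#: last flowering date so a full 200-day cycle always has coverage
FIXTURE_WEATHER_START = dt.date(2018, 1, 1)
FIXTURE_WEATHER_END = dt.date(2021, 3, 31)

_KNOWN_KEYS = {
    "soil": {"name"},
    "treatment": {"weather_file", "co2_ppm", "sowing_is_flowering", "cycle_cap_days"},
    "observation": {"lai", "fsolar_obs", "biomass_per_plant_kg", "harvest_index"},
    "species": {
        "tbase", "topt", "maxt", "extremet", "s_co2", "s_water",
        "fsolar_max", "initial_fsolar",
    },
}
_REQUIRED_KEYS = {
    "soil": {"name"},
    "treatment": {"weather_file", "co2_ppm", "cycle_cap_days"},
    "observation": {"harvest_index"},
    "species": {"tbase", "topt", "maxt", "extremet", "s_co2", "s_water"},
}


class ConfigError(ValueError):
    """Raised for a missing file, missing key, or out-of-range value."""


@dataclass(frozen=True)
class ConfigBundle:
    """Validated contents of the seven-file configuration directory."""

    directory: Path
    soil: Mapping[str, str]
    treatment: Mapping[str, str]
    observation: Mapping[str, str]
    cultivars: Mapping[str, tuple[float, float]]  # cultivar -> (i50a, i50b)
    species: Mapping[str, str]
    regions: Mapping[str, RegionParams]
    samples: tuple[FloweringSample, ...]
    warnings: tuple[str, ...] = ()

    @property
    def co2_ppm(self) -> float:
        return float(self.treatment["co2_ppm"])

    def species_params(self, cultivar: str = "ICS95") -> SpeciesCultivarParams:
        """Assemble the physiological parameter set for one cultivar."""
        if cultivar not in self.cultivars:
            raise ConfigError(f"unknown cultivar {cultivar!r}")
        i50a, i50b = self.cultivars[cultivar]
        sp = {k: float(v) for k, v in self.species.items()}
        return SpeciesCultivarParams(
            tbase=sp["tbase"],
            topt=sp["topt"],
            maxt=sp["maxt"],
            extremet=sp["extremet"],
            s_co2=sp["s_co2"],
            s_water=sp["s_water"],
            i50a=i50a,
            i50b=i50b,
            hi=float(self.observation["harvest_index"]),
            fsolar_max=sp.get("fsolar_max", 0.94),
            initial_fsolar=sp.get("initial_fsolar", 0.01),
            cycle_cap=int(float(self.treatment["cycle_cap_days"])),
        )

    def samples_for(self, region: str) -> list[FloweringSample]:
        return [s for s in self.samples if s.region == region]


def _read_kv(path: Path) -> dict[str, str]:
    if not path.exists():
        raise ConfigError(f"missing configuration file: {path.name}")
    df = pd.read_csv(path, dtype=str)
    if not {"variable", "value"} <= set(df.columns):
        raise ConfigError(f"{path.name}: expected 'variable,value' columns")
    return dict(zip(df["variable"].str.strip(), df["value"].astype(str).str.strip()))


def _check_keys(section: str, data: Mapping[str, str], warn_list: list[str]) -> None:
    missing = _REQUIRED_KEYS[section] - set(data)
    if missing:
        raise ConfigError(f"{section}.csv: missing required key(s): {sorted(missing)}")
    unknown = set(data) - _KNOWN_KEYS[section]
    for k in sorted(unknown):
        msg = f"{section}.csv: unknown key {k!r} ignored"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=3)


def load_config(directory: str | Path) -> ConfigBundle:
    """Load and validate the seven-file bundle from ``directory``.

    Unknown keys produce warnings; missing files or required keys, and
    out-of-range values (e.g. a harvest index ≥ 1), raise
    :class:`ConfigError` naming the offender.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigError(f"config directory not found: {directory}")
    absent = [f for f in CONFIG_FILES if not (directory / f).exists()]
    if absent:
        raise ConfigError(f"missing configuration file(s): {absent}")

    warn_list: list[str] = []
    soil = _read_kv(directory / "soil.csv")
    treatment = _read_kv(directory / "treatment.csv")
    observation = _read_kv(directory / "observation.csv")
    for section, data in (("soil", soil), ("treatment", treatment),
                          ("observation", observation)):
        _check_keys(section, data, warn_list)
    species_raw = _read_kv(directory / "species.csv")
    _check_keys("species", species_raw, warn_list)

    hi = float(observation["harvest_index"])
    if not (0.0 < hi < 1.0):
        raise ConfigError(f"observation.csv: harvest_index {hi} outside (0, 1)")

    cdf = pd.read_csv(directory / "cultivar.csv")
    need = {"cultivar", "i50a", "i50b"}
    if not need <= set(cdf.columns):
        raise ConfigError(f"cultivar.csv: expected columns {sorted(need)}")
    cultivars = {
        str(r.cultivar): (float(r.i50a), float(r.i50b)) for r in cdf.itertuples()
    }

    rdf = pd.read_csv(directory / "regions.csv")
    need = {"region", "tsum", "rue", "observed_yield"}
    if not need <= set(rdf.columns):
        raise ConfigError(f"regions.csv: expected columns {sorted(need)}")
    try:
        regions = {
            str(r.region): RegionParams(
                str(r.region), float(r.tsum), float(r.rue), float(r.observed_yield)
            )
            for r in rdf.itertuples()
        }
    except ValueError as exc:
        raise ConfigError(f"regions.csv: {exc}") from exc

    samples = tuple(read_samples(directory / "samples.csv"))

    bundle = ConfigBundle(
        directory=directory,
        soil=soil,
        treatment=treatment,
        observation=observation,
        cultivars=cultivars,
        species=species_raw,
        regions=regions,
        samples=samples,
        warnings=tuple(warn_list),
    )
    try:
        bundle.species_params(next(iter(cultivars)))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return bundle


def read_samples(path: str | Path) -> list[FloweringSample]:
    """Read flowering-date field samples from CSV."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"missing configuration file: {path.name}")
    df = pd.read_csv(path)
    need = {"region", "flowering_date"}
    if not need <= set(df.columns):
        raise ConfigError(f"{path.name}: expected at least columns {sorted(need)}")

    def opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    out = []
    for _, row in df.iterrows():
        harvest = None
        if "observed_harvest_date" in df.columns and not pd.isna(
            row["observed_harvest_date"]
        ):
            harvest = pd.Timestamp(row["observed_harvest_date"]).date()
        out.append(
            FloweringSample(
                region=str(row["region"]),
                flowering_date=pd.Timestamp(row["flowering_date"]).date(),
                observed_harvest_date=harvest,
                observed_yield=opt(row, "observed_yield"),
                plant_density=opt(row, "plant_density"),
                tree_age=opt(row, "tree_age"),
                pods_per_ha=opt(row, "pods_per_ha"),
            )
        )
    return out


def write_samples(samples: Sequence[FloweringSample], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in samples:
        rows.append(
            {
                "region": s.region,
                "flowering_date": s.flowering_date.isoformat(),
                "observed_harvest_date": (
                    s.observed_harvest_date.isoformat()
                    if s.observed_harvest_date
                    else ""
                ),
                "observed_yield": "" if s.observed_yield is None else s.observed_yield,
                "plant_density": "" if s.plant_density is None else s.plant_density,
                "tree_age": "" if s.tree_age is None else s.tree_age,
                "pods_per_ha": "" if s.pods_per_ha is None else s.pods_per_ha,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def reconstructed_flowering_dates(
    n: int = SAMPLES_PER_REGION,
    first: dt.date = FD_FIRST,
    last: dt.date = FD_LAST,
) -> list[dt.date]:
    """``n`` evenly spaced flowering dates spanning the field campaign.

    The individual per-farm dates were never published; this deterministic
    reconstruction keeps the campaign's endpoints and its roughly monthly
    cadence (23 dates over ~347 days).
    """
    span = (last - first).days
    offsets = np.round(np.linspace(0, span, n)).astype(int)
    return [first + dt.timedelta(days=int(o)) for o in offsets]


def write_default_config(
    directory: str | Path,
    samples: Sequence[FloweringSample] | None = None,
    weather_file: str = "weather_{region}.csv",
) -> Path:
    """Write the shipped default bundle (calibrated parameter tables).

    Without an explicit sample list, the reconstructed flowering dates are
    written for every region with the regional observed yield attached to
    each sample (region-level yield is the only published observation).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def kv(name: str, pairs: Sequence[tuple[str, object]]) -> None:
        pd.DataFrame(pairs, columns=["variable", "value"]).to_csv(
            directory / name, index=False
        )

    kv("soil.csv", [("name", "Loamy sand4")])
    kv(
        "treatment.csv",
        [
            ("weather_file", weather_file),
            ("co2_ppm", 400),
            ("sowing_is_flowering", "true"),
            ("cycle_cap_days", 200),
        ],
    )
    kv(
        "observation.csv",
        [
            ("lai", 1.8),
            ("fsolar_obs", 0.70),
            ("biomass_per_plant_kg", 40),
            ("harvest_index", 0.3),
        ],
    )
    pd.DataFrame(
        [("ICS95", 680, 680), ("CCN51", 680, 680)],
        columns=["cultivar", "i50a", "i50b"],
    ).to_csv(directory / "cultivar.csv", index=False)
    kv(
        "species.csv",
        [
            ("tbase", 10), ("topt", 26), ("maxt", 35), ("extremet", 40),
            ("s_co2", 0.09), ("s_water", 0),
            ("fsolar_max", 0.94), ("initial_fsolar", 0.01),
        ],
    )
    pd.DataFrame(
        [
            (r.region, r.tsum, r.rue, r.observed_yield)
            for r in REGION_PARAMS.values()
        ],
        columns=["region", "tsum", "rue", "observed_yield"],
    ).to_csv(directory / "regions.csv", index=False)

    if samples is None:
        samples = []
        for region, params in REGION_PARAMS.items():
            for fd in reconstructed_flowering_dates():
                samples.append(
                    FloweringSample(
                        region=region,
                        flowering_date=fd,
                        observed_harvest_date=fd + dt.timedelta(days=180),
                        observed_yield=params.observed_yield,
                    )
                )
    write_samples(samples, directory / "samples.csv")
    return directory


def load_weather_for_region(bundle: ConfigBundle, region: str) -> WeatherSeries:
    """Resolve and read the weather file named by the treatment section."""
    pattern = bundle.treatment["weather_file"]
    path = bundle.directory / pattern.format(region=region)
    if not path.exists():
        raise ConfigError(f"weather file not found: {path}")
    return WeatherSeries.from_csv(path, location=region)


def make_fixtures(directory: str | Path, seed: int) -> Path:
    """Write a complete synthetic study driven by one seed.

    Per region: synthetic weather for 2018-01-01..2021-03-31 (the study
    window extended past the last flowering date so every 200-day cycle
    has coverage) and 23 evenly spaced flowering dates from 2019-07-12 to
    2020-06-23 (115 samples in all) whose observed yields sit within ±10%
    of the regional calibration value.  Plus the seven-file bundle.
    Identical seeds reproduce the directory byte for byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(ARCHETYPES) + 1)
    noise_rng = np.random.default_rng(children[-1])

    samples: list[FloweringSample] = []
    for child, (region, archetype) in zip(children, ARCHETYPES.items()):
        wseed = int(child.generate_state(1)[0] % (2**31))
        series = generate_synthetic_weather(
            archetype, FIXTURE_WEATHER_START, FIXTURE_WEATHER_END, seed=wseed
        )
        series.to_csv(directory / f"weather_{region}.csv")
        base_yield = REGION_PARAMS[region].observed_yield
        for fd in reconstructed_flowering_dates():
            noisy = base_yield * (1.0 + noise_rng.uniform(-0.10, 0.10))
            samples.append(
                FloweringSample(
                    region=region,
                    flowering_date=fd,
                    observed_harvest_date=fd + dt.timedelta(days=180),
                    observed_yield=round(noisy, 1),
                    plant_density=float(noise_rng.integers(600, 1200)),
                    tree_age=float(noise_rng.integers(4, 25)),
                )
            )
    write_default_config(directory, samples=samples)
    return directory
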
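import datetime as dt

import pandas as pd
import pytest

from cacaosim import ARCHETYPES, WeatherSeries, generate_synthetic_weather


def make_constant_series(
    tmean: float,
    n_days: int = 420,
    start: dt.date = dt.date(2019, 1, 1),
    srad: float = 15.0,
    diurnal: float = 10.0,
    location: str = "constant",
) -> WeatherSeries:
    """Flat weather: every day has the same mean temperature and radiation."""
    idx = pd.date_range(start, periods=n_days, freq="D")
    df = pd.DataFrame(
        {
            "date": idx,
            "tmax": tmean + diurnal / 2.0,
            "tmin": tmean - diurnal / 2.0,
            "srad": srad,
            "rain": 0.0,
        }
    )
    return WeatherSeries(location, df)


@pytest.fixture
def constant_series():
    return make_constant_series


@pytest.fixture(scope="session")
def apartado_weather() -> WeatherSeries:
    """Three-and-a-half years of seeded Apartado-like weather."""
    return generate_synthetic_weather(
        ARCHETYPES["Apartado"], dt.date(2018, 1, 1), dt.date(2021, 6, 30), seed=42
    )
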
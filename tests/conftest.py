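import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

from gxesim.phenology import CultivarPhenologyParams
from gxesim.synth import GeneratorConfig, generate_dataset
from gxesim.weather import ClimateParams, WeatherSeries, generate_weather

# EC schemas on short synthetic seasons routinely drop zero-variance columns;
# that warning is expected throughout the suite.
warnings.filterwarnings("ignore", message="dropping .* zero-variance EC columns")


def constant_weather(tmean=15.0, days=420, latitude=48.0, start="1999-09-01", rain=1.0, rg=900.0):
    dates = pd.date_range(start, periods=days, freq="D")
    df = pd.DataFrame(
        {
            "date": dates,
            "tmin": tmean - 4.0,
            "tmax": tmean + 4.0,
            "radiation": rg,
            "rain": rain,
        }
    )
    return WeatherSeries(df, latitude=latitude)


@pytest.fixture(scope="session")
def tiny_network():
    """A small but complete synthetic trial network (shared, read-only)."""
    cfg = GeneratorConfig(
        years=4, locations=5, cultivars=20, snps=120, presence_prob=0.45, seed=42
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def one_season_weather():
    return generate_weather(48.0, 2005, ClimateParams(), seed=3, location="Lx")


@pytest.fixture
def ref_params():
    return CultivarPhenologyParams()
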
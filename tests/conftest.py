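import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aerhome import (
    Home,
    IncomeClass,
    RoadType,
    SyntheticConfig,
    generate_study,
)
from aerhome.synthetic import MeasurementConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def home():
    """A typical older low-income single-storey home."""
    return Home(
        home_id="H1",
        year_built=1942,
        floor_area=120.0,
        n_stories=1,
        income_class=IncomeClass.LOW_INCOME,
        shelter_class=4,
        road_type=RoadType.LTLD,
    )


@pytest.fixture
def home_conventional():
    return Home(
        home_id="H2",
        year_built=1990,
        floor_area=150.0,
        n_stories=2,
        income_class=IncomeClass.CONVENTIONAL,
        shelter_class=3,
        road_type=RoadType.HTHD,
    )


@pytest.fixture(scope="session")
def study():
    """One two-year synthetic study with measurement noise (shared, read-only)."""
    return generate_study(
        SyntheticConfig(seed=42), start=dt.date(2010, 1, 1), end=dt.date(2011, 12, 31)
    )


@pytest.fixture(scope="session")
def noise_free_study():
    """Same design with the measurement error switched off."""
    cfg = SyntheticConfig(
        measurement=MeasurementConfig(accuracy_cv=0.0, precision_cv=0.0), seed=42
    )
    return generate_study(cfg, start=dt.date(2010, 1, 1), end=dt.date(2011, 12, 31))


@pytest.fixture
def constant_weather():
    """One week of perfectly constant hourly weather."""
    index = pd.date_range("2010-06-01", periods=7 * 24, freq="h")
    return pd.DataFrame(
        {"t_out_c": np.full(len(index), 14.0), "wind_speed_ms": np.full(len(index), 3.0)},
        index=pd.DatetimeIndex(index, name="timestamp"),
    )
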
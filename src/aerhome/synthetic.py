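"""Synthetic study generator: housing stock, weather, window diaries and
tracer-style AER measurements.

The generator emulates the structure of a near-road cohort AER study so the
calibration / evaluation / prediction pipeline can be exercised end-to-end
with no external data:

* a housing stock of 213 homes split 52/46/115 across the HTHD/HTLD/LTLD
  road strata, built 1888-2007, with both income classes and homes on both
  sides of the 1979 construction-age cutoff;
* hourly weather with a seasonal outdoor-temperature cycle (large winter
  indoor-outdoor difference, near-zero in summer), diurnal variation and
  autocorrelated daily noise, and a nonnegative skewed autocorrelated wind
  speed with a median near 3.5 m/s (about 12.6 km/h);
* a window-opening diary whose opening probability rises as the
  indoor-outdoor temperature difference shrinks (windows open on mild days);
* AER "measurements" on five consecutive days per home in each of two
  seasonal intensives, generated from the LBLX forward model and corrupted
  with multiplicative lognormal error: a per-home bias component with CV in
  the tracer-accuracy band (20-25%) and a per-day replicate component with
  CV in the precision band (5-15%).

Everything is reproducible from a single root seed; stages draw from
independent child streams.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_types import (
    Home,
    HousingKind,
    IncomeClass,
    RoadType,
    ValidationError,
)
from .leakage import DEFAULT_LEAKAGE_PARAMS, LeakageParamSet
from .models import (
    DEFAULT_COEFFICIENTS,
    NaturalVentConfig,
    daily_weather_means,
    lblx_aer,
)

__all__ = [
    "StockConfig",
    "WeatherConfig",
    "DiaryConfig",
    "MeasurementConfig",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_stock",
    "generate_calibration_stock",
    "generate_weather",
    "generate_diaries",
    "generate_measurements",
    "generate_study",
]


@dataclass(frozen=True)
class StockConfig:
    """Housing-stock attributes: sizes and category mixes."""

    n_homes: int = 213
    year_range: tuple[int, int] = (1888, 2007)
    floor_area_median: float = 115.0  # m2, lognormal median
    floor_area_log_sd: float = 0.32
    floor_area_range: tuple[float, float] = (55.0, 420.0)
    stories_probs: tuple[float, float, float] = (0.50, 0.45, 0.05)  # 1, 2, 3 stories
    p_low_income: float = 0.70
    shelter_probs: tuple[float, ...] = (0.0, 0.05, 0.25, 0.55, 0.15)  # classes 1..5
    road_mix: tuple[int, int, int] = (52, 46, 115)  # HTHD, HTLD, LTLD weights


@dataclass(frozen=True)
class WeatherConfig:
    """Seasonal-sinusoid temperature and autocorrelated lognormal wind."""

    t_mean: float = 9.8  # °C annual mean
    t_season_amp: float = 14.0  # °C, half peak-to-trough of the annual cycle
    t_diurnal_amp: float = 4.0  # °C, half peak-to-trough within a day
    t_daily_sd: float = 3.5  # °C, day-to-day AR(1) noise
    t_daily_ar1: float = 0.7
    t_hourly_sd: float = 0.6  # °C, hour-to-hour white noise
    coldest_doy: int = 15  # day of year of the seasonal minimum
    wind_median: float = 3.5  # m/s at 10 m
    wind_log_sd: float = 0.45
    wind_ar1: float = 0.95  # hourly autocorrelation of log wind


@dataclass(frozen=True)
class DiaryConfig:
    """Window-opening behaviour coupled to mild weather."""

    # P(open) = 0.5 at T_out = T_in, falling to ~0.15 at a 12 K difference
    # (typical fall/spring day) and ~2% in deep winter
    logit_at_equal_temp: float = 0.0
    logit_slope_per_k: float = 0.15  # decrease per K of |T_in − T_out|
    extra_windows_mean: float = 0.7  # windows open = 1 + Poisson(this)
    fraction_range: tuple[float, float] = (0.25, 1.0)
    t_in_reference: float = 24.0  # °C


@dataclass(frozen=True)
class MeasurementConfig:
    """Tracer-style multiplicative measurement error and sampling design."""

    accuracy_cv: float = 0.225  # per-home bias CV (accuracy band 20-25%)
    precision_cv: float = 0.10  # per-day replicate CV (precision band 5-15%)
    days_per_season: int = 5
    t_in_sd: float = 0.8  # °C scatter of daily-mean indoor temperature
    aer_guard: tuple[float, float] = (0.01, 10.0)  # physical guard range, 1/h


@dataclass(frozen=True)
class SyntheticConfig:
    stock: StockConfig = field(default_factory=StockConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    diary: DiaryConfig = field(default_factory=DiaryConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    true_params: LeakageParamSet = field(default_factory=LeakageParamSet)
    seed: int = 0


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` across categories."""
    w = np.asarray(weights, dtype=float)
    ideal = total * w / w.sum()
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _draw_home(
    home_id: str,
    year_built: int,
    road: RoadType,
    income: IncomeClass,
    cfg: StockConfig,
    rng: np.random.Generator,
    housing_kind: HousingKind = HousingKind.DETACHED,
) -> Home:
    lo, hi = cfg.floor_area_range
    area = float(
        np.clip(
            cfg.floor_area_median * math.exp(rng.normal(0.0, cfg.floor_area_log_sd)),
            lo,
            hi,
        )
    )
    stories = int(rng.choice([1, 2, 3], p=np.asarray(cfg.stories_probs) / sum(cfg.stories_probs)))
    shelter = int(
        rng.choice(
            np.arange(1, 6), p=np.asarray(cfg.shelter_probs) / sum(cfg.shelter_probs)
        )
    )
    return Home(
        home_id=home_id,
        year_built=year_built,
        floor_area=round(area, 1),
        n_stories=stories,
        income_class=income,
        shelter_class=shelter,
        road_type=road,
        housing_kind=housing_kind,
    )


def generate_stock(cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> list[Home]:
    """A reproducible housing stock with the configured category mixes.

    Road-type counts follow largest-remainder allocation of ``road_mix``
    (213 homes with the default mix give exactly 52/46/115).  Years built
    are uniform over ``year_range``, so the stock straddles the 1979
    construction-age cutoff.
    """
    s = cfg.stock
    if s.n_homes < 1:
        raise ValidationError("n_homes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    road_counts = _allocate(s.n_homes, s.road_mix)
    homes: list[Home] = []
    i = 0
    for road, count in zip((RoadType.HTHD, RoadType.HTLD, RoadType.LTLD), road_counts):
        for _ in range(count):
            year = int(rng.integers(s.year_range[0], s.year_range[1] + 1))
            income = (
                IncomeClass.LOW_INCOME
                if rng.random() < s.p_low_income
                else IncomeClass.CONVENTIONAL
            )
            kind = HousingKind.APARTMENT if rng.random() < 0.04 else HousingKind.DETACHED
            homes.append(_draw_home(f"H{i:03d}", year, road, income, s, rng, kind))
            i += 1
    return homes


def generate_calibration_stock(
    cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[Home]:
    """The 24-home measurement subset: a cluster of 23 older homes
    (17 low-income, 6 conventional, built 1900-1969) plus one newer home
    (1997), with road-type counts 7/5/12 across HTHD/HTLD/LTLD."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    s = cfg.stock
    roads = (
        [RoadType.HTHD] * 7 + [RoadType.HTLD] * 5 + [RoadType.LTLD] * 12
    )
    incomes = [IncomeClass.LOW_INCOME] * 17 + [IncomeClass.CONVENTIONAL] * 6
    years = rng.integers(1900, 1970, size=23)
    order = rng.permutation(23)
    homes = []
    for i in range(23):
        homes.append(
            _draw_home(
                f"C{i:02d}", int(years[i]), roads[i], incomes[order[i]], s, rng
            )
        )
    homes.append(_draw_home("C23", 1997, roads[23], IncomeClass.CONVENTIONAL, s, rng))
    return homes


def generate_weather(
    cfg: SyntheticConfig,
    start: _dt.date,
    end: _dt.date,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Hourly weather from ``start`` 00:00 through ``end`` 23:00 inclusive.

    Outdoor temperature = annual sinusoid + diurnal sinusoid + AR(1) daily
    noise + white hourly noise; wind speed is exp(AR(1)) around the
    configured median.  A zero-amplitude, zero-noise configuration yields a
    constant series.
    """
    if end < start:
        raise ValidationError(f"reversed date range: {start} .. {end}")
    w = cfg.weather
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    index = pd.date_range(
        pd.Timestamp(start), pd.Timestamp(end) + pd.Timedelta(hours=23), freq="h"
    )
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy()
    seasonal = w.t_mean - w.t_season_amp * np.cos(
        2.0 * np.pi * (doy - w.coldest_doy) / 365.25
    )
    diurnal = w.t_diurnal_amp * np.cos(2.0 * np.pi * (hour - 15) / 24.0)

    n_days = (end - start).days + 1
    daily = np.empty(n_days)
    innov = rng.normal(0.0, 1.0, size=n_days)
    daily[0] = w.t_daily_sd * innov[0]
    for d in range(1, n_days):
        daily[d] = w.t_daily_ar1 * daily[d - 1] + w.t_daily_sd * math.sqrt(
            1.0 - w.t_daily_ar1**2
        ) * innov[d]
    day_idx = ((index.normalize() - pd.Timestamp(start)).days).to_numpy()
    t_out = seasonal + diurnal + daily[day_idx] + rng.normal(0.0, w.t_hourly_sd, len(index))

    log_wind = np.empty(len(index))
    mu = math.log(w.wind_median)
    innov = rng.normal(0.0, 1.0, size=len(index))
    log_wind[0] = mu + w.wind_log_sd * innov[0]
    c = w.wind_log_sd * math.sqrt(1.0 - w.wind_ar1**2)
    for t in range(1, len(index)):
        log_wind[t] = mu + w.wind_ar1 * (log_wind[t - 1] - mu) + c * innov[t]
    wind = np.exp(log_wind)

    out = pd.DataFrame(
        {"t_out_c": t_out, "wind_speed_ms": wind}, index=index
    )
    out.index.name = "timestamp"
    return out


def generate_diaries(
    homes: Sequence[Home],
    weather: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    dates: Optional[Sequence[_dt.date]] = None,
) -> pd.DataFrame:
    """Window-opening diary rows for the given homes and dates.

    The daily opening probability is a logistic function of the daily-mean
    indoor-outdoor temperature difference: windows open most often when
    outdoor temperature is close to the indoor reference.  Only open days
    are recorded (absent rows mean closed, as in a field diary).
    """
    d = cfg.diary
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    means = daily_weather_means(weather)
    if dates is not None:
        wanted = set(dates)
        means = means[[dt in wanted for dt in means.index]]
    rows = []
    for home in homes:
        dt_abs = np.abs(d.t_in_reference - means["t_out_c"].to_numpy())
        p_open = expit(d.logit_at_equal_temp - d.logit_slope_per_k * dt_abs)
        opens = rng.random(len(means)) < p_open
        for date, is_open in zip(means.index, opens):
            if not is_open:
                continue
            n_windows = 1 + rng.poisson(d.extra_windows_mean)
            frac = rng.uniform(*d.fraction_range)
            rows.append(
                {
                    "home_id": home.home_id,
                    "date": date,
                    "open_window_days": round(float(n_windows * frac), 3),
                }
            )
    return pd.DataFrame(rows, columns=["home_id", "date", "open_window_days"])


def _mean_one_lognormal(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def generate_measurements(
    stock: Sequence[Home],
    weather: pd.DataFrame,
    diaries: pd.DataFrame,
    true_params: LeakageParamSet,
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    period_starts: Optional[Sequence[_dt.date]] = None,
    coeffs=DEFAULT_COEFFICIENTS,
    vent_cfg: NaturalVentConfig = NaturalVentConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tracer-style daily AER measurements for every home in ``stock``.

    For each measurement period every home gets ``days_per_season``
    consecutive daily values.  The true AER comes from the LBLX forward
    model driven by 24-h mean weather, the home's diary and its daily-mean
    indoor temperature; the measured value is truth × per-home bias ×
    per-day noise, both multiplicative lognormal with mean 1.

    Returns (measurements, indoor_temperatures, truth): measurements with
    columns home_id/date/aer_per_h, indoor temperatures with
    home_id/date/t_in_c, and the noise-free truth with home_id/date/aer_per_h.
    """
    m = cfg.measurement
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    means = daily_weather_means(weather)
    if period_starts is None:
        first = weather.index.min().date()
        period_starts = [first]
    diary_map = {}
    if len(diaries):
        diary_map = {
            (r.home_id, pd.Timestamp(r.date).date()): float(r.open_window_days)
            for r in diaries.itertuples(index=False)
        }

    meas_rows, tin_rows, truth_rows = [], [], []
    guard_lo, guard_hi = m.aer_guard
    for home in stock:
        bias = float(_mean_one_lognormal(m.accuracy_cv, None, rng))
        for start in period_starts:
            for k in range(m.days_per_season):
                date = start + _dt.timedelta(days=k)
                if date not in means.index:
                    raise ValidationError(
                        f"weather does not cover measurement day {date}"
                    )
                t_out = float(means.loc[date, "t_out_c"])
                u = float(means.loc[date, "wind_speed_ms"])
                t_in = float(
                    cfg.diary.t_in_reference + rng.normal(0.0, m.t_in_sd)
                )
                owd = diary_map.get((home.home_id, date), 0.0)
                truth = lblx_aer(
                    home, t_in, t_out, u, owd, coeffs, true_params, vent_cfg
                )
                if not guard_lo <= truth <= guard_hi:
                    warnings.warn(
                        f"home {home.home_id}: true AER {truth:.3g} 1/h outside "
                        f"guard range [{guard_lo}, {guard_hi}]",
                        stacklevel=2,
                    )
                noise = float(_mean_one_lognormal(m.precision_cv, None, rng))
                meas_rows.append(
                    {"home_id": home.home_id, "date": date, "aer_per_h": truth * bias * noise}
                )
                tin_rows.append({"home_id": home.home_id, "date": date, "t_in_c": t_in})
                truth_rows.append(
                    {"home_id": home.home_id, "date": date, "aer_per_h": truth}
                )
    cols = ["home_id", "date", "aer_per_h"]
    return (
        pd.DataFrame(meas_rows, columns=cols),
        pd.DataFrame(tin_rows, columns=["home_id", "date", "t_in_c"]),
        pd.DataFrame(truth_rows, columns=cols),
    )


@dataclass
class SyntheticStudy:
    """Bundle of one complete synthetic study."""

    config: SyntheticConfig
    stock: list[Home]  # full stock, calibration subset first
    calibration_homes: list[Home]
    weather: pd.DataFrame
    diaries: pd.DataFrame  # calibration homes, measurement days only
    measurements: pd.DataFrame
    indoor_temps: pd.DataFrame
    truth: pd.DataFrame
    period_starts: list[_dt.date]


def generate_study(
    cfg: SyntheticConfig = SyntheticConfig(),
    start: _dt.date = _dt.date(2010, 1, 1),
    end: _dt.date = _dt.date(2012, 12, 31),
) -> SyntheticStudy:
    """One full synthetic study: stock, multi-year hourly weather, and a
    two-season measurement campaign (five consecutive days per home in a
    fall and a spring window) on a 24-home calibration subset that is part
    of the stock."""
    rng_stock, rng_cal, rng_weather, rng_diary, rng_meas = _child_rngs(cfg.seed, 5)
    calibration = generate_calibration_stock(cfg, rng_cal)
    rest_cfg = SyntheticConfig(
        stock=StockConfig(
            **{
                **cfg.stock.__dict__,
                "n_homes": max(cfg.stock.n_homes - len(calibration), 0),
            }
        ),
        weather=cfg.weather,
        diary=cfg.diary,
        measurement=cfg.measurement,
        true_params=cfg.true_params,
        seed=cfg.seed,
    )
    stock = calibration + generate_stock(rest_cfg, rng_stock)
    weather = generate_weather(cfg, start, end, rng_weather)
    period_starts = [
        _dt.date(start.year, 10, 4),
        _dt.date(start.year + 1, 4, 11),
    ]
    meas_dates = [
        p + _dt.timedelta(days=k)
        for p in period_starts
        for k in range(cfg.measurement.days_per_season)
    ]
    diaries = generate_diaries(calibration, weather, cfg, rng_diary, dates=meas_dates)
    measurements, indoor_temps, truth = generate_measurements(
        calibration,
        weather,
        diaries,
        cfg.true_params,
        cfg,
        rng_meas,
        period_starts=period_starts,
    )
    return SyntheticStudy(
        config=cfg,
        stock=stock,
        calibration_homes=calibration,
        weather=weather,
        diaries=diaries,
        measurements=measurements,
        indoor_temps=indoor_temps,
        truth=truth,
        period_starts=list(period_starts),
    )
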
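"""Shared domain types and unit conventions.

Unit conventions used throughout the package
--------------------------------------------
* temperatures are degrees Celsius (absolute-temperature conversions happen
  locally where a formula requires Kelvin),
* wind speed is stored in m/s at the 10 m reference height (file readers
  convert km/h or knot sources, see :mod:`aerhome.io`),
* lengths and areas are metres / square metres,
* air exchange rates (AER) are air changes per hour (1/h),
* a "day" is a midnight-to-midnight calendar day in local study time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "IncomeClass",
    "AgeRegime",
    "RoadType",
    "HousingKind",
    "Home",
    "IndoorTempPolicy",
    "LeakageParams",
    "CoefficientTable",
    "PollutantParams",
    "derive_volume",
    "building_height",
    "validate_weather",
    "validate_diary",
    "STORY_HEIGHT_M",
    "ROOF_HEIGHT_M",
    "DEFAULT_CEILING_HEIGHT_M",
    "MS_PER_KMH",
    "MS_PER_KNOT",
]


class ValidationError(ValueError):
    """An input violates a domain invariant (the message names the field)."""


class ConfigurationError(ValueError):
    """A lookup (coefficient, parameter regime) cannot be resolved."""


#: storey height used to derive building height from the number of stories, m
STORY_HEIGHT_M = 2.5
#: roof allowance added on top of the stories, m
ROOF_HEIGHT_M = 0.5
#: typical residential ceiling height (8 ft), m
DEFAULT_CEILING_HEIGHT_M = 2.44

MS_PER_KMH = 1.0 / 3.6
MS_PER_KNOT = 0.514444


class IncomeClass(str, Enum):
    """Household income stratum used to select the leakage regression."""

    LOW_INCOME = "low_income"
    CONVENTIONAL = "conventional"


class AgeRegime(str, Enum):
    """Construction-age regime for leakage parameters (cutoff year 1979)."""

    OLDER = "older"
    NEWER = "newer"


class RoadType(str, Enum):
    """Traffic stratum of the home: high/low traffic x high/low diesel."""

    HTHD = "HTHD"
    HTLD = "HTLD"
    LTLD = "LTLD"


class HousingKind(str, Enum):
    DETACHED = "detached"
    APARTMENT = "apartment"
    TOWNHOME = "townhome"


@dataclass(frozen=True)
class Home:
    """Static building attributes of one residence.

    Parameters
    ----------
    home_id
        Opaque identifier, unique within a housing stock.
    year_built
        Calendar year of construction, within [1850, current year].
    floor_area
        Conditioned floor area in m² (> 0).
    n_stories
        Number of stories, 1–3.
    income_class
        Low-income (below 125% of the poverty guideline) or conventional;
        selects the leakage-area regression.
    shelter_class
        Ordinal local wind-shelter category (1 = exposed … 5 = heavily
        sheltered) used to look up the wind coefficient.
    road_type
        Traffic stratum of the nearest major road.
    housing_kind
        Detached home, apartment or townhome.  All kinds share the same
        leakage regression.
    ceiling_height
        Interior ceiling height in m (default 2.44 m, i.e. 8 ft).
    volume
        Interior volume in m³.  When omitted it is derived as
        ``floor_area * ceiling_height``.
    """

    home_id: str
    year_built: int
    floor_area: float
    n_stories: int
    income_class: IncomeClass
    shelter_class: int
    road_type: RoadType
    housing_kind: HousingKind = HousingKind.DETACHED
    ceiling_height: float = DEFAULT_CEILING_HEIGHT_M
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.floor_area > 0:
            raise ValidationError(
                f"home {self.home_id!r}: floor_area must be > 0, got {self.floor_area}"
            )
        if not self.ceiling_height > 0:
            raise ValidationError(
                f"home {self.home_id!r}: ceiling_height must be > 0, "
                f"got {self.ceiling_height}"
            )
        if self.volume is not None and not self.volume > 0:
            raise ValidationError(
                f"home {self.home_id!r}: volume must be > 0, got {self.volume}"
            )
        if self.n_stories not in (1, 2, 3):
            raise ValidationError(
                f"home {self.home_id!r}: n_stories must be 1, 2 or 3, "
                f"got {self.n_stories}"
            )
        current_year = _dt.date.today().year
        if not 1850 <= self.year_built <= current_year:
            raise ValidationError(
                f"home {self.home_id!r}: year_built {self.year_built} outside "
                f"[1850, {current_year}]"
            )
        if not 1 <= int(self.shelter_class) <= 5:
            raise ValidationError(
                f"home {self.home_id!r}: shelter_class must be in 1..5, "
                f"got {self.shelter_class}"
            )


def derive_volume(home: Home) -> float:
    """Interior volume of ``home`` in m³.

    An explicitly supplied volume takes precedence; otherwise the volume is
    the floor area multiplied by the ceiling height.
    """
    if home.volume is not None:
        return float(home.volume)
    return float(home.floor_area * home.ceiling_height)


def building_height(home: Home) -> float:
    """Building height H in m: 2.5 m per storey plus a 0.5 m roof allowance."""
    return STORY_HEIGHT_M * home.n_stories + ROOF_HEIGHT_M


@dataclass(frozen=True)
class IndoorTempPolicy:
    """How indoor temperature T_in is assigned.

    ``constant`` applies ``constant_value`` (default 24 °C, the study-wide
    median indoor temperature) at every hour of every day.  ``measured_series``
    applies a per-(home, day) 24-h mean uniformly across that day's hours;
    ``series`` must then hold columns ``home_id``, ``date``, ``t_in_c``.
    """

    mode: str = "constant"
    constant_value: float = 24.0
    series: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "measured_series"):
            raise ValidationError(f"unknown indoor-temperature mode {self.mode!r}")
        if not 10.0 <= self.constant_value <= 35.0:
            raise ValidationError(
                f"constant indoor temperature {self.constant_value} °C outside [10, 35]"
            )
        if self.mode == "measured_series":
            if self.series is None:
                raise ValidationError("measured_series mode requires a series")
            missing = {"home_id", "date", "t_in_c"} - set(self.series.columns)
            if missing:
                raise ValidationError(f"indoor-temperature series missing {missing}")

    def t_in_for(self, home_id: str, date: _dt.date) -> float:
        """T_in (°C) applied on ``date`` in home ``home_id``."""
        if self.mode == "constant":
            return self.constant_value
        assert self.series is not None
        sel = self.series[
            (self.series["home_id"] == home_id)
            & (pd.to_datetime(self.series["date"]).dt.date == date)
        ]
        if sel.empty:
            return self.constant_value  # fall back for unmeasured days
        return float(sel["t_in_c"].iloc[0])


@dataclass(frozen=True)
class LeakageParams:
    """One (β0, β1, β2) triple of the normalized-leakage regression.

    NL = exp(β0 + β1·year_built + β2·floor_area); β0 and β1 are
    dimensionless (β1 per calendar year), β2 is per m².  Each triple is valid
    for exactly one (house type, age regime) stratum.
    """

    beta0: float
    beta1: float
    beta2: float
    house_type: IncomeClass
    age_regime: AgeRegime
    ci_low: Optional[tuple[float, float, float]] = None
    ci_high: Optional[tuple[float, float, float]] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2], dtype=float)


@dataclass(frozen=True)
class CoefficientTable:
    """Stack and wind coefficients of the leakage airflow model.

    Unit convention: with the leakage area expressed in cm² the airflow
    comes out in L/s, so ``stack`` entries carry (L/s)²·cm⁻⁴·K⁻¹ and
    ``wind`` entries (L/s)²·cm⁻⁴·(m/s)⁻².  ``stack`` is keyed by number of
    stories, ``wind`` by (stories, shelter class).
    """

    stack: Mapping[int, float]
    wind: Mapping[tuple[int, int], float]
    convention: str = "A_leak cm2, Q L/s, k_s (L/s)2/cm4/K, k_w (L/s)2/cm4/(m/s)2"

    def __post_init__(self) -> None:
        for k, v in self.stack.items():
            if not v > 0:
                raise ValidationError(f"stack coefficient for {k} stories must be > 0")
        for k, v in self.wind.items():
            if not v > 0:
                raise ValidationError(f"wind coefficient for {k} must be > 0")

    def resolve(self, n_stories: int, shelter_class: int) -> tuple[float, float]:
        """(k_s, k_w) for a building, or a ConfigurationError naming the keys."""
        try:
            ks = self.stack[n_stories]
        except KeyError:
            raise ConfigurationError(
                f"no stack coefficient for {n_stories} stories"
            ) from None
        try:
            kw = self.wind[(n_stories, shelter_class)]
        except KeyError:
            raise ConfigurationError(
                f"no wind coefficient for (stories={n_stories}, "
                f"shelter_class={shelter_class})"
            ) from None
        return float(ks), float(kw)


@dataclass(frozen=True)
class PollutantParams:
    """Penetration coefficient P and first-order indoor loss rate k_d (1/h).

    The defaults (P=0.9, k_d=1.0 1/h) are reported values for PM2.5.
    """

    penetration: float = 0.9
    deposition: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetration <= 1.0:
            raise ValidationError(
                f"penetration must be in [0, 1], got {self.penetration}"
            )
        if self.deposition < 0.0:
            raise ValidationError(f"deposition must be >= 0, got {self.deposition}")


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check a weather table: DatetimeIndex strictly increasing, required
    columns ``t_out_c`` and ``wind_speed_ms``, nonnegative wind.

    Returns the (unmodified) frame so the call composes with readers.
    """
    if not isinstance(weather.index, pd.DatetimeIndex):
        raise ValidationError("weather table must be indexed by timestamp")
    if len(weather) == 0:
        raise ValidationError("weather table is empty")
    missing = {"t_out_c", "wind_speed_ms"} - set(weather.columns)
    if missing:
        raise ValidationError(f"weather table missing columns {missing}")
    if not weather.index.is_monotonic_increasing or weather.index.has_duplicates:
        raise ValidationError("weather timestamps must be strictly increasing")
    wind = weather["wind_speed_ms"].to_numpy(dtype=float)
    if np.nanmin(wind) < 0:
        raise ValidationError("wind_speed_ms must be >= 0")
    return weather


def validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Check a window-opening diary: columns home_id/date/open_window_days,
    values >= 0.  Absent (home, day) rows mean all windows closed."""
    missing = {"home_id", "date", "open_window_days"} - set(diary.columns)
    if missing:
        raise ValidationError(f"window diary missing columns {missing}")
    if len(diary) and (diary["open_window_days"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("open_window_days must be >= 0")
    return diary
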
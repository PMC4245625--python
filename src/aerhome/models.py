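"""LBL and LBLX air-exchange-rate models.

The LBL model predicts the airflow through unintentional envelope openings
(leakage) from the stack effect (indoor-outdoor temperature difference) and
the wind effect::

    Q_LBL = A_leak * sqrt(k_s |T_in - T_out| + k_w U^2)

The LBLX model adds natural ventilation through open windows, combining the
leakage and natural-ventilation airflows in quadrature::

    Q_LBLX = sqrt(Q_LBL^2 + Q_nat^2),   Q_nat = sqrt(Q_nat_wind^2 + Q_nat_stack^2)

with a wind-driven term ``Q_nat_wind = C_v A_nat U`` and a buoyancy-driven
term ``Q_nat_stack = C_D A_nat sqrt(2 g dH_NPL |T_in - T_out| / max{T_in,
T_out})`` (the temperature ratio on the absolute scale).  The AER is the
airflow divided by the building volume.

Coefficient convention (see :class:`aerhome.core_types.CoefficientTable`):
A_leak in cm², Q_LBL in L/s, k_s in (L/s)²·cm⁻⁴·K⁻¹, k_w in
(L/s)²·cm⁻⁴·(m/s)⁻²; AER [1/h] = 3.6 · Q[L/s] / V[m³].  The shipped
coefficient defaults follow the ASHRAE residential basic-model tables
(stack coefficient by stories, wind coefficient by stories × shelter class)
and are fully overridable via configuration.

All airflow functions broadcast over NumPy arrays in the weather arguments.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_types import (
    CoefficientTable,
    Home,
    IndoorTempPolicy,
    ValidationError,
    building_height,
    derive_volume,
    validate_diary,
    validate_weather,
)
from .leakage import DEFAULT_LEAKAGE_PARAMS, LeakageParamSet, leakage_area

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "NaturalVentConfig",
    "lbl_airflow",
    "lbl_aer",
    "natural_wind_flow",
    "natural_stack_flow",
    "natural_vent_area",
    "lblx_aer",
    "predict_daily_series",
]

logger = logging.getLogger(__name__)

_CELSIUS_TO_KELVIN = 273.15
_CM2_PER_M2 = 1.0e4
_LS_PER_M3S = 1.0e3

# ASHRAE residential basic-model coefficients.
# Stack coefficient by number of stories, (L/s)^2 cm^-4 K^-1.
_ASHRAE_STACK = {1: 0.000145, 2: 0.000290, 3: 0.000435}
# Wind coefficient by (stories, shelter class 1..5), (L/s)^2 cm^-4 (m/s)^-2.
_ASHRAE_WIND = {
    (1, 1): 0.000319, (2, 1): 0.000420, (3, 1): 0.000494,
    (1, 2): 0.000246, (2, 2): 0.000325, (3, 2): 0.000382,
    (1, 3): 0.000174, (2, 3): 0.000231, (3, 3): 0.000271,
    (1, 4): 0.000104, (2, 4): 0.000137, (3, 4): 0.000161,
    (1, 5): 0.000032, (2, 5): 0.000042, (3, 5): 0.000049,
}

DEFAULT_COEFFICIENTS = CoefficientTable(stack=_ASHRAE_STACK, wind=_ASHRAE_WIND)


@dataclass(frozen=True)
class NaturalVentConfig:
    """Constants of the open-window natural-ventilation terms.

    Defaults: opening effectiveness C_v = 0.30, discharge coefficient
    C_D = 0.65, a 0.06 m² opening per window (0.6 m × 0.1 m), lower-opening
    midpoint at 0.91 m, and the neutral pressure level at one-half of the
    building height.
    """

    opening_effectiveness: float = 0.30
    discharge_coeff: float = 0.65
    window_open_area_each: float = 0.06
    lower_opening_midpoint: float = 0.91
    npl_fraction: float = 0.5
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in (
            "opening_effectiveness",
            "discharge_coeff",
            "window_open_area_each",
            "lower_opening_midpoint",
            "gravity",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 < self.npl_fraction < 1.0:
            raise ValidationError("npl_fraction must be in (0, 1)")


def lbl_airflow(a_leak, t_in, t_out, u, k_s: float, k_w: float):
    """Leakage airflow Q_LBL in L/s.

    ``a_leak`` is the effective leakage area in m² (converted to cm²
    internally per the coefficient convention); temperatures in °C, wind in
    m/s.  Zero exactly when both driving forces vanish.
    """
    a_cm2 = np.asarray(a_leak, dtype=float) * _CM2_PER_M2
    if np.any(a_cm2 <= 0):
        raise ValidationError("a_leak must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any(u[np.isfinite(u)] < 0):
        raise ValidationError("wind speed must be >= 0")
    dt = np.abs(np.asarray(t_in, dtype=float) - np.asarray(t_out, dtype=float))
    q = a_cm2 * np.sqrt(k_s * dt + k_w * u * u)
    return q if q.ndim else float(q)


def lbl_aer(
    home: Home,
    t_in,
    t_out,
    u,
    coeffs: CoefficientTable = DEFAULT_COEFFICIENTS,
    param_set: LeakageParamSet = DEFAULT_LEAKAGE_PARAMS,
):
    """LBL (leakage-only) AER in 1/h: 3.6 · Q_LBL[L/s] / V[m³]."""
    k_s, k_w = coeffs.resolve(home.n_stories, home.shelter_class)
    q = lbl_airflow(leakage_area(home, param_set), t_in, t_out, u, k_s, k_w)
    return 3.6 * q / derive_volume(home)


def natural_wind_flow(a_nat, u, cfg: NaturalVentConfig = NaturalVentConfig()):
    """Wind-driven natural ventilation C_v · A_nat · U in m³/s."""
    a = np.asarray(a_nat, dtype=float)
    if np.any(a < 0):
        raise ValidationError("a_nat must be >= 0")
    q = cfg.opening_effectiveness * a * np.asarray(u, dtype=float)
    return q if q.ndim else float(q)


def natural_stack_flow(
    a_nat, t_in, t_out, home: Home, cfg: NaturalVentConfig = NaturalVentConfig()
):
    """Buoyancy-driven natural ventilation through openings in m³/s.

    dH_NPL is the height from the lower-opening midpoint to the neutral
    pressure level.  The temperature difference is the Celsius difference
    (identical in Kelvin); the denominator max{T_in, T_out} is converted to
    Kelvin, keeping the ratio physical near 0 °C.
    """
    a = np.asarray(a_nat, dtype=float)
    if np.any(a < 0):
        raise ValidationError("a_nat must be >= 0")
    dh_npl = cfg.npl_fraction * building_height(home) - cfg.lower_opening_midpoint
    if dh_npl <= 0:
        raise ValidationError(
            f"home {home.home_id!r}: opening midpoint at or above the neutral "
            f"pressure level (dH_NPL = {dh_npl:.3f} m)"
        )
    t_in = np.asarray(t_in, dtype=float)
    t_out = np.asarray(t_out, dtype=float)
    dt = np.abs(t_in - t_out)
    t_max_k = np.maximum(t_in, t_out) + _CELSIUS_TO_KELVIN
    q = cfg.discharge_coeff * a * np.sqrt(2.0 * cfg.gravity * dh_npl * dt / t_max_k)
    return q if q.ndim else float(q)


def natural_vent_area(open_window_days, cfg: NaturalVentConfig = NaturalVentConfig()):
    """Inlet opening area A_nat in m²: one-half of the total open-window
    area, with the diary value (windows open × fraction of day) scaled by the
    per-window opening area.  Negative diary values are clamped to zero."""
    owd = np.asarray(open_window_days, dtype=float)
    if np.any(owd < 0):
        logger.warning("negative open_window_days clamped to 0")
        owd = np.clip(owd, 0.0, None)
    a = 0.5 * owd * cfg.window_open_area_each
    return a if a.ndim else float(a)


def lblx_aer(
    home: Home,
    t_in,
    t_out,
    u,
    open_window_days=0.0,
    coeffs: CoefficientTable = DEFAULT_COEFFICIENTS,
    param_set: LeakageParamSet = DEFAULT_LEAKAGE_PARAMS,
    cfg: NaturalVentConfig = NaturalVentConfig(),
):
    """LBLX (leakage + natural ventilation) AER in 1/h.

    Reduces exactly (bit-for-bit) to :func:`lbl_aer` when all windows are
    closed: the quadrature uses ``hypot``, and ``hypot(q, 0) == q``.
    """
    k_s, k_w = coeffs.resolve(home.n_stories, home.shelter_class)
    q_lbl = lbl_airflow(leakage_area(home, param_set), t_in, t_out, u, k_s, k_w)
    a_nat = natural_vent_area(open_window_days, cfg)
    q_w = natural_wind_flow(a_nat, u, cfg)
    q_s = natural_stack_flow(a_nat, t_in, t_out, home, cfg)
    q_nat = np.hypot(q_w, q_s) * _LS_PER_M3S
    q = np.hypot(q_lbl, q_nat)
    return 3.6 * q / derive_volume(home)


def _fill_short_gaps(col: pd.Series, max_gap_hours: int) -> pd.Series:
    """Linear interpolation across NaN runs of at most ``max_gap_hours``
    consecutive hours; longer runs (and edge gaps) stay NaN."""
    isna = col.isna()
    if not isna.any():
        return col
    filled = col.interpolate(method="time", limit_area="inside")
    run_id = (isna != isna.shift()).cumsum()
    run_len = isna.groupby(run_id).transform("sum")
    filled[isna & (run_len > max_gap_hours)] = np.nan
    return filled


def _hourly_grid(weather: pd.DataFrame, max_gap_hours: int) -> pd.DataFrame:
    """Reindex to a complete hourly grid and fill permissible gaps."""
    grid = pd.date_range(weather.index.min(), weather.index.max(), freq="h")
    out = weather.reindex(grid)
    for col in ("t_out_c", "wind_speed_ms"):
        out[col] = _fill_short_gaps(out[col], max_gap_hours)
    return out


def predict_daily_series(
    stock: Sequence[Home],
    weather: pd.DataFrame,
    policy: IndoorTempPolicy = IndoorTempPolicy(),
    model: str = "lbl",
    diaries: Optional[pd.DataFrame] = None,
    coeffs: CoefficientTable = DEFAULT_COEFFICIENTS,
    param_set: LeakageParamSet = DEFAULT_LEAKAGE_PARAMS,
    vent_cfg: NaturalVentConfig = NaturalVentConfig(),
    max_gap_hours: int = 6,
) -> pd.DataFrame:
    """Daily (24-h average) AER for every home in ``stock``.

    Hourly AER is computed from hourly outdoor temperature and wind speed,
    then averaged midnight-to-midnight.  Hours missing from the weather
    series are linearly interpolated across gaps of at most
    ``max_gap_hours``; a day with any remaining invalid hour is flagged
    (``aer_per_h`` = NaN) rather than silently dropped.

    Parameters
    ----------
    stock
        Homes to predict for (non-empty).
    weather
        Hourly weather indexed by timestamp with columns ``t_out_c`` and
        ``wind_speed_ms``.
    policy
        Indoor-temperature policy (constant 24 °C by default).
    model
        ``"lbl"`` (leakage only) or ``"lblx"`` (leakage + open windows,
        requires ``diaries``; absent diary rows mean windows closed).
    diaries
        Optional window diary with columns home_id/date/open_window_days.

    Returns
    -------
    DataFrame with columns home_id, date, aer_per_h, model, n_valid_hours.
    """
    if len(stock) == 0:
        raise ValidationError("empty housing stock")
    if model not in ("lbl", "lblx"):
        raise ValidationError(f"unknown model {model!r}")
    validate_weather(weather)
    if diaries is not None:
        validate_diary(diaries)

    hourly = _hourly_grid(weather, max_gap_hours)
    t_out = hourly["t_out_c"].to_numpy(dtype=float)
    u = hourly["wind_speed_ms"].to_numpy(dtype=float)
    valid = np.isfinite(t_out) & np.isfinite(u)
    dates = hourly.index.normalize()

    # per-day hour slices (positions into the hourly grid)
    positions = np.arange(len(hourly))
    codes, unique_days = pd.factorize(dates)
    groups = {
        unique_days[i].date(): positions[codes == i] for i in range(len(unique_days))
    }

    diary_map: dict[tuple[str, _dt.date], float] = {}
    if diaries is not None and len(diaries):
        d = diaries.copy()
        d["date"] = pd.to_datetime(d["date"]).dt.date
        diary_map = {
            (r.home_id, r.date): float(r.open_window_days)
            for r in d.itertuples(index=False)
        }

    # hours are only used where valid; placeholder values elsewhere
    t_out_safe = np.where(valid, t_out, 0.0)
    u_safe = np.where(valid, u, 0.0)

    records = []
    n_hours = len(hourly)
    for home in stock:
        k_s, k_w = coeffs.resolve(home.n_stories, home.shelter_class)
        a_leak = leakage_area(home, param_set)
        volume = derive_volume(home)

        t_in = np.empty(n_hours)
        owd = np.zeros(n_hours)
        for day, idx in groups.items():
            t_in[idx] = policy.t_in_for(home.home_id, day)
            if model == "lblx":
                owd[idx] = diary_map.get((home.home_id, day), 0.0)

        q_lbl = lbl_airflow(a_leak, t_in, t_out_safe, u_safe, k_s, k_w)
        if model == "lblx":
            a_nat = natural_vent_area(owd, vent_cfg)
            q_w = natural_wind_flow(a_nat, u_safe, vent_cfg)
            q_s = natural_stack_flow(a_nat, t_in, t_out_safe, home, vent_cfg)
            q = np.hypot(q_lbl, np.hypot(q_w, q_s) * _LS_PER_M3S)
        else:
            q = q_lbl
        aer = 3.6 * q / volume

        for day, idx in groups.items():
            day_valid = valid[idx]
            n_valid = int(day_valid.sum())
            complete = n_valid == 24 and len(idx) == 24
            records.append(
                {
                    "home_id": home.home_id,
                    "date": day,
                    "aer_per_h": float(np.mean(aer[idx])) if complete else np.nan,
                    "model": model,
                    "n_valid_hours": n_valid,
                }
            )
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["home_id", "date"]).reset_index(drop=True)


def daily_weather_means(weather: pd.DataFrame) -> pd.DataFrame:
    """24-h average outdoor temperature and wind speed per calendar day.

    This is the time-matched averaging path used for calibration against
    24-h integrated AER measurements (daily-mean inputs into the models,
    rather than daily means of hourly AER).  Only complete 24-hour days are
    returned.
    """
    validate_weather(weather)
    by_day = weather.groupby(weather.index.normalize())
    means = by_day.mean()
    counts = by_day.count().min(axis=1)
    means = means[counts == 24]
    means.index = [ts.date() for ts in means.index]
    means.index.name = "date"
    return means
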
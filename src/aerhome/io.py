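"""CSV and YAML readers/writers for the package's file interfaces.

Formats
-------
homes.csv
    home_id, year_built, floor_area_m2, n_stories, ceiling_height_m,
    volume_m3 (optional, blank when derived), income_class, shelter_class,
    road_type, housing_kind
weather.csv
    timestamp (ISO-8601, hourly or daily), t_out_c, wind_speed — the source
    wind unit is declared at read time ("m/s", "km/h" or "knots") and
    converted to the internal m/s
windows.csv
    home_id, date, open_window_days
aer_measured.csv / aer_daily.csv
    home_id, date, aer_per_h (daily predictions additionally carry model
    and n_valid_hours)
coefficients.yaml
    stack coefficient by stories, wind coefficient by stories × shelter
    class, plus the unit-convention string
leakage_params.yaml
    beta0/beta1/beta2 (and optional 95% CI bounds) per
    (house_type, age_regime) block, plus the age cutoff year
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core_types import (
    AgeRegime,
    CoefficientTable,
    Home,
    HousingKind,
    IncomeClass,
    LeakageParams,
    MS_PER_KMH,
    MS_PER_KNOT,
    RoadType,
    ValidationError,
    validate_diary,
    validate_weather,
)
from .leakage import LeakageParamSet

__all__ = [
    "read_homes",
    "write_homes",
    "read_weather",
    "write_weather",
    "read_windows",
    "write_windows",
    "read_aer",
    "write_aer",
    "read_coefficients",
    "write_coefficients",
    "read_leakage_params",
    "write_leakage_params",
]

_WIND_FACTORS = {"m/s": 1.0, "km/h": MS_PER_KMH, "knots": MS_PER_KNOT}

PathLike = Union[str, Path]


def write_homes(homes: Sequence[Home], path: PathLike) -> None:
    rows = []
    for h in homes:
        rows.append(
            {
                "home_id": h.home_id,
                "year_built": h.year_built,
                "floor_area_m2": h.floor_area,
                "n_stories": h.n_stories,
                "ceiling_height_m": h.ceiling_height,
                "volume_m3": "" if h.volume is None else h.volume,
                "income_class": h.income_class.value,
                "shelter_class": h.shelter_class,
                "road_type": h.road_type.value,
                "housing_kind": h.housing_kind.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_homes(path: PathLike) -> list[Home]:
    df = pd.read_csv(path)
    required = {
        "home_id",
        "year_built",
        "floor_area_m2",
        "n_stories",
        "income_class",
        "shelter_class",
        "road_type",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"homes file {path} missing columns {missing}")
    homes = []
    for r in df.itertuples(index=False):
        volume = getattr(r, "volume_m3", None)
        if volume is not None and (pd.isna(volume) or volume == ""):
            volume = None
        ceiling = getattr(r, "ceiling_height_m", None)
        homes.append(
            Home(
                home_id=str(r.home_id),
                year_built=int(r.year_built),
                floor_area=float(r.floor_area_m2),
                n_stories=int(r.n_stories),
                income_class=IncomeClass(r.income_class),
                shelter_class=int(r.shelter_class),
                road_type=RoadType(r.road_type),
                housing_kind=HousingKind(getattr(r, "housing_kind", "detached")),
                ceiling_height=float(ceiling) if ceiling is not None and not pd.isna(ceiling) else 2.44,
                volume=float(volume) if volume is not None else None,
            )
        )
    return homes


def read_weather(path: PathLike, units: str = "m/s") -> pd.DataFrame:
    """Weather series with wind converted from the declared source unit."""
    if units not in _WIND_FACTORS:
        raise ValidationError(
            f"unknown wind unit {units!r}; expected one of {sorted(_WIND_FACTORS)}"
        )
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "t_out_c", "wind_speed"} - set(df.columns)
    if missing:
        raise ValidationError(f"weather file {path} missing columns {missing}")
    out = pd.DataFrame(
        {
            "t_out_c": df["t_out_c"].to_numpy(dtype=float),
            "wind_speed_ms": df["wind_speed"].to_numpy(dtype=float)
            * _WIND_FACTORS[units],
        },
        index=pd.DatetimeIndex(df["timestamp"], name="timestamp"),
    )
    return validate_weather(out)


def write_weather(weather: pd.DataFrame, path: PathLike) -> None:
    """Write a weather table (wind in the internal m/s)."""
    validate_weather(weather)
    out = pd.DataFrame(
        {
            "timestamp": weather.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "t_out_c": weather["t_out_c"].to_numpy(),
            "wind_speed": weather["wind_speed_ms"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def read_windows(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_diary(df)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_windows(diary: pd.DataFrame, path: PathLike) -> None:
    validate_diary(diary).to_csv(path, index=False)


def read_aer(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"home_id", "date", "aer_per_h"} - set(df.columns)
    if missing:
        raise ValidationError(f"AER file {path} missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_aer(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, index=False)


def write_coefficients(table: CoefficientTable, path: PathLike) -> None:
    wind: dict[int, dict[int, float]] = {}
    for (stories, shelter), value in sorted(table.wind.items()):
        wind.setdefault(int(stories), {})[int(shelter)] = float(value)
    doc = {
        "convention": table.convention,
        "stack": {int(k): float(v) for k, v in sorted(table.stack.items())},
        "wind": wind,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_coefficients(path: PathLike) -> CoefficientTable:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        stack = {int(k): float(v) for k, v in doc["stack"].items()}
        wind = {
            (int(st), int(sh)): float(v)
            for st, by_shelter in doc["wind"].items()
            for sh, v in by_shelter.items()
        }
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed coefficients file {path}: {exc}") from exc
    return CoefficientTable(
        stack=stack, wind=wind, convention=doc.get("convention", "")
    )


def write_leakage_params(param_set: LeakageParamSet, path: PathLike) -> None:
    doc: dict = {"cutoff_year": param_set.cutoff_year}
    for (ht, ar), p in param_set.entries.items():
        block = doc.setdefault(ht.value, {})
        entry = {"beta0": float(p.beta0), "beta1": float(p.beta1), "beta2": float(p.beta2)}
        if p.ci_low is not None:
            entry["ci_low"] = [float(v) for v in p.ci_low]
        if p.ci_high is not None:
            entry["ci_high"] = [float(v) for v in p.ci_high]
        block[ar.value] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_leakage_params(path: PathLike) -> LeakageParamSet:
    doc = yaml.safe_load(Path(path).read_text())
    entries = {}
    for ht in IncomeClass:
        for ar in AgeRegime:
            try:
                e = doc[ht.value][ar.value]
            except (KeyError, TypeError):
                raise ValidationError(
                    f"leakage parameter file {path} missing block "
                    f"({ht.value}, {ar.value})"
                ) from None
            entries[(ht, ar)] = LeakageParams(
                beta0=float(e["beta0"]),
                beta1=float(e["beta1"]),
                beta2=float(e["beta2"]),
                house_type=ht,
                age_regime=ar,
                ci_low=tuple(e["ci_low"]) if "ci_low" in e else None,
                ci_high=tuple(e["ci_high"]) if "ci_high" in e else None,
            )
    return LeakageParamSet(
        entries=entries, cutoff_year=int(doc.get("cutoff_year", 1979))
    )
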
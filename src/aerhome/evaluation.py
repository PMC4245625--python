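"""Model-evaluation metrics for paired predicted/measured daily AER.

Per-record metrics: relative difference ε = 100·(pred − meas)/meas (%) and
absolute difference Δ = pred − meas (1/h); positive values mean the model
overestimated.  Correlations are "weighted" by first replacing every
record of a home with that home's mean (one effective point per home), so
homes with many measurement days do not dominate; R² is the square of the
weighted Pearson correlation.

Quantiles use linear interpolation between order statistics (type 7, the
NumPy default).
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import Home, ValidationError
from .leakage import DEFAULT_CUTOFF_YEAR

__all__ = [
    "relative_difference",
    "absolute_difference",
    "weighted_correlation",
    "tag_pairs",
    "summarize",
    "season_of",
]

_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def season_of(date) -> str:
    """Meteorological season of a date (winter = Dec–Feb, etc.)."""
    return _SEASONS[pd.Timestamp(date).month]


def relative_difference(pred, meas):
    """Signed relative difference ε in percent; requires measured > 0."""
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if np.any(m <= 0):
        raise ValidationError("relative difference undefined for measured AER <= 0")
    out = 100.0 * (p - m) / m
    return out if out.ndim else float(out)


def absolute_difference(pred, meas):
    """Signed absolute difference Δ = pred − meas in 1/h."""
    out = np.asarray(pred, dtype=float) - np.asarray(meas, dtype=float)
    return out if out.ndim else float(out)


def _home_means(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs.groupby("home_id")[["predicted", "measured"]].mean()


def weighted_correlation(pairs: pd.DataFrame, flavor: str = "pearson") -> float:
    """Correlation of per-home mean predicted vs mean measured AER.

    ``pairs`` needs columns home_id/predicted/measured with at least two
    homes.  ``flavor`` is ``"pearson"`` or ``"spearman"`` (ranks of the home
    means).  Returns NaN when a series has zero variance across home means
    (correlation undefined).
    """
    if flavor not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation flavor {flavor!r}")
    means = _home_means(pairs)
    if len(means) < 2:
        raise ValidationError("weighted correlation needs >= 2 homes")
    x = means["predicted"].to_numpy()
    y = means["measured"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if flavor == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def tag_pairs(
    pairs: pd.DataFrame,
    homes: Sequence[Home],
    diaries: Optional[pd.DataFrame] = None,
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
) -> pd.DataFrame:
    """Attach stratum tags (season, road_type, age_regime, window_status)
    to a predicted/measured pair table.

    A (home, day) is "open" iff the diary shows open_window_days > 0;
    absent diary rows mean closed.
    """
    by_id = {h.home_id: h for h in homes}
    unknown = set(pairs["home_id"]) - set(by_id)
    if unknown:
        raise ValidationError(f"pairs reference unknown homes {sorted(unknown)}")
    out = pairs.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out["season"] = [season_of(d) for d in out["date"]]
    out["road_type"] = [by_id[h].road_type.value for h in out["home_id"]]
    out["age_regime"] = [
        "older" if by_id[h].year_built <= cutoff_year else "newer"
        for h in out["home_id"]
    ]
    open_days: set[tuple[str, _dt.date]] = set()
    if diaries is not None and len(diaries):
        d = diaries[diaries["open_window_days"] > 0]
        open_days = {
            (r.home_id, pd.Timestamp(r.date).date()) for r in d.itertuples(index=False)
        }
    out["window_status"] = [
        "open" if (h, d) in open_days else "closed"
        for h, d in zip(out["home_id"], out["date"])
    ]
    return out


_METRIC_COLS = ("eps", "delta", "abs_eps", "abs_delta")

# canonical levels per stratum: empty levels still get a row (n = 0)
_CANONICAL_LEVELS = {
    "season": ("winter", "spring", "summer", "fall"),
    "road_type": ("HTHD", "HTLD", "LTLD"),
    "age_regime": ("older", "newer"),
    "window_status": ("closed", "open"),
}


def _stratum_row(name: str, level: str, sub: pd.DataFrame) -> dict:
    row: dict = {"stratum": name, "level": level, "n": len(sub)}
    if len(sub) == 0:
        return row
    for col in _METRIC_COLS:
        v = sub[col].to_numpy()
        row[f"{col}_q25"], row[f"{col}_median"], row[f"{col}_q75"] = np.percentile(
            v, [25, 50, 75]
        )
    if sub["home_id"].nunique() >= 2:
        r = weighted_correlation(sub, "pearson")
        row["pearson_r"] = r
        row["spearman_rho"] = weighted_correlation(sub, "spearman")
        row["r2"] = r * r
    return row


def summarize(
    tagged_pairs: pd.DataFrame,
    strata: Sequence[str] = ("season", "road_type", "age_regime", "window_status"),
) -> pd.DataFrame:
    """Per-stratum and overall evaluation summary.

    Expects the output of :func:`tag_pairs`.  Each row holds n, the
    25th/50th/75th percentiles of ε, Δ, |ε| and |Δ|, and — when the stratum
    spans at least two homes — the weighted Pearson r, Spearman ρ and R².
    """
    pairs = tagged_pairs.copy()
    pairs["eps"] = relative_difference(pairs["predicted"], pairs["measured"])
    pairs["delta"] = absolute_difference(pairs["predicted"], pairs["measured"])
    pairs["abs_eps"] = pairs["eps"].abs()
    pairs["abs_delta"] = pairs["delta"].abs()

    rows = [_stratum_row("overall", "all", pairs)]
    for stratum in strata:
        if stratum not in pairs.columns:
            raise ValidationError(f"pairs are not tagged with {stratum!r}")
        observed = list(pairs[stratum].unique())
        levels = list(_CANONICAL_LEVELS.get(stratum, ())) + [
            lv for lv in observed if lv not in _CANONICAL_LEVELS.get(stratum, ())
        ]
        for level in levels:
            rows.append(_stratum_row(stratum, str(level), pairs[pairs[stratum] == level]))
    return pd.DataFrame(rows)
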
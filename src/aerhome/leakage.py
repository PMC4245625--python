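"""Effective air leakage area from the normalized-leakage regression.

The envelope leakiness of a home is summarised by the effective leakage
area ``A_leak = NL / NF`` where

* ``NL = exp(β0 + β1·year_built + β2·floor_area)`` is the dimensionless
  normalized leakage, with one (β0, β1, β2) triple per (house type,
  construction-age regime) stratum, and
* ``NF = (1000 / floor_area) · (H / 2.5)^0.3`` is the normalization factor
  (1/m² for floor area in m²), H the building height in m.

``A_leak`` therefore carries m² here; conversion to cm² happens only inside
:mod:`aerhome.models` where the airflow coefficient convention requires it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .core_types import (
    AgeRegime,
    ConfigurationError,
    Home,
    IncomeClass,
    LeakageParams,
    ValidationError,
    building_height,
)

__all__ = [
    "DEFAULT_CUTOFF_YEAR",
    "DEFAULT_LEAKAGE_PARAMS",
    "LeakageParamSet",
    "normalized_leakage",
    "normalization_factor",
    "leakage_area",
]

#: homes built in this year or before use the "older" parameter regime
DEFAULT_CUTOFF_YEAR = 1979

# exp() overflows double precision just above 709
_MAX_EXPONENT = 700.0


def _default_entries() -> dict[tuple[IncomeClass, AgeRegime], LeakageParams]:
    """Shipped defaults: field-calibrated triples for the older regime and
    literature-reported triples for the newer regime."""
    return {
        (IncomeClass.LOW_INCOME, AgeRegime.OLDER): LeakageParams(
            beta0=65.5,
            beta1=-3.40e-2,
            beta2=-7.33e-4,
            house_type=IncomeClass.LOW_INCOME,
            age_regime=AgeRegime.OLDER,
            ci_low=(29.0, -5.29e-2, -9.34e-3),
            ci_high=(102.0, -1.51e-2, 7.88e-3),
        ),
        (IncomeClass.CONVENTIONAL, AgeRegime.OLDER): LeakageParams(
            beta0=56.9,
            beta1=-2.91e-2,
            beta2=-5.65e-3,
            house_type=IncomeClass.CONVENTIONAL,
            age_regime=AgeRegime.OLDER,
            ci_low=(17.7, -4.91e-2, -1.39e-2),
            ci_high=(96.2, -9.07e-3, 2.58e-3),
        ),
        (IncomeClass.LOW_INCOME, AgeRegime.NEWER): LeakageParams(
            beta0=11.1,
            beta1=-5.37e-3,
            beta2=-4.18e-3,
            house_type=IncomeClass.LOW_INCOME,
            age_regime=AgeRegime.NEWER,
        ),
        (IncomeClass.CONVENTIONAL, AgeRegime.NEWER): LeakageParams(
            beta0=20.7,
            beta1=-1.07e-2,
            beta2=-2.20e-3,
            house_type=IncomeClass.CONVENTIONAL,
            age_regime=AgeRegime.NEWER,
        ),
    }


@dataclass(frozen=True)
class LeakageParamSet:
    """The four leakage regressions of a run, keyed by stratum.

    ``entries`` must resolve every (house_type, age_regime) combination;
    ``cutoff_year`` splits the age regimes (built in the cutoff year or
    before -> older).
    """

    entries: Mapping[tuple[IncomeClass, AgeRegime], LeakageParams] = field(
        default_factory=_default_entries
    )
    cutoff_year: int = DEFAULT_CUTOFF_YEAR

    def __post_init__(self) -> None:
        for ht in IncomeClass:
            for ar in AgeRegime:
                if (ht, ar) not in self.entries:
                    raise ConfigurationError(
                        f"leakage parameter set missing stratum ({ht.value}, {ar.value})"
                    )

    def age_regime_of(self, home: Home) -> AgeRegime:
        return AgeRegime.OLDER if home.year_built <= self.cutoff_year else AgeRegime.NEWER

    def resolve(self, home: Home) -> LeakageParams:
        """The unique parameter triple applying to ``home``."""
        return self.entries[(home.income_class, self.age_regime_of(home))]

    def replaced(self, params: LeakageParams) -> "LeakageParamSet":
        """A copy with the stratum of ``params`` replaced (used after fitting)."""
        entries = dict(self.entries)
        entries[(params.house_type, params.age_regime)] = params
        return LeakageParamSet(entries=entries, cutoff_year=self.cutoff_year)


#: module-level default parameter set
DEFAULT_LEAKAGE_PARAMS = LeakageParamSet()


def normalized_leakage(home: Home, params: LeakageParams) -> float:
    """NL = exp(β0 + β1·year_built + β2·floor_area), dimensionless.

    ``params`` must belong to the stratum of ``home`` (house type matching
    the income class); the age regime is checked by the caller that resolved
    the triple, so only the house type is re-validated here.
    """
    if params.house_type != home.income_class:
        raise ConfigurationError(
            f"home {home.home_id!r} is {home.income_class.value} but parameters "
            f"are for {params.house_type.value}"
        )
    exponent = params.beta0 + params.beta1 * home.year_built + params.beta2 * home.floor_area
    if not math.isfinite(exponent) or abs(exponent) > _MAX_EXPONENT:
        raise ValidationError(
            f"home {home.home_id!r}: normalized-leakage exponent {exponent!r} "
            "out of range"
        )
    return math.exp(exponent)


def normalization_factor(home: Home) -> float:
    """NF = (1000 / floor_area) · (H / 2.5)^0.3 in 1/m²."""
    if not home.floor_area > 0:
        raise ValidationError(f"home {home.home_id!r}: floor_area must be > 0")
    h = building_height(home)
    return (1000.0 / home.floor_area) * (h / 2.5) ** 0.3


def leakage_area(home: Home, param_set: LeakageParamSet = DEFAULT_LEAKAGE_PARAMS) -> float:
    """Effective leakage area A_leak = NL / NF in m².

    Constant over time for a given home; strictly positive.
    """
    params = param_set.resolve(home)
    return normalized_leakage(home, params) / normalization_factor(home)
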
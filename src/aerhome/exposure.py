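"""Infiltration factor, indoor concentration and exposure from AER.

Single-zone mass balance for an outdoor-generated pollutant with
penetration coefficient P and first-order indoor loss rate k_d::

    dC_in/dt = P * AER * C_out - (AER + k_d) * C_in

At steady state C_in_ss = F_inf * C_out_ss with the infiltration factor
F_inf = P * AER / (AER + k_d).  Time-activity-weighted exposure under
steady-state outdoor concentration is E = C_out_ss * (f_in * F_inf +
(1 - f_in)) where f_in is the fraction of time spent indoors at home.

The model is linear in concentration and unit-agnostic: concentrations come
out in whatever units they go in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_types import PollutantParams, ValidationError

__all__ = [
    "ExposureInputs",
    "infiltration_factor",
    "steady_state_indoor",
    "dynamic_indoor",
    "exposure",
]


@dataclass(frozen=True)
class ExposureInputs:
    """Inputs of the steady-state exposure equation."""

    f_in: float
    pollutant: PollutantParams
    aer: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_in <= 1.0:
            raise ValidationError(f"f_in must be in [0, 1], got {self.f_in}")


def infiltration_factor(pollutant: PollutantParams, aer):
    """F_inf = P · AER / (AER + k_d), dimensionless in [0, P].

    Increasing in AER; tends to P as AER grows and as k_d vanishes.
    """
    a = np.asarray(aer, dtype=float)
    if np.any(a < 0):
        raise ValidationError("AER must be >= 0")
    if pollutant.deposition == 0.0 and np.any(a == 0.0):
        raise ValidationError("F_inf undefined for AER = k_d = 0")
    f = pollutant.penetration * a / (a + pollutant.deposition)
    return f if f.ndim else float(f)


def steady_state_indoor(c_out_ss, pollutant: PollutantParams, aer):
    """Steady-state indoor concentration C_in_ss = F_inf · C_out_ss."""
    c = np.asarray(c_out_ss, dtype=float)
    if np.any(c < 0):
        raise ValidationError("outdoor concentration must be >= 0")
    out = infiltration_factor(pollutant, aer) * c
    return out if np.ndim(out) else float(out)


def dynamic_indoor(
    c_out: pd.Series,
    aer: pd.Series | float,
    pollutant: PollutantParams = PollutantParams(),
    c_in_initial: float = 0.0,
) -> pd.Series:
    """Indoor concentration time series from the dynamic mass balance.

    ``c_out`` is a time-indexed outdoor concentration series; ``aer`` is a
    matching series (or a constant, 1/h).  Both are treated as
    piecewise-constant over each interval of the grid, on which the balance
    has the exact solution::

        C(t + dt) = C_ss + (C(0) - C_ss) * exp(-(AER + k_d) dt)

    with C_ss = P·AER·C_out / (AER + k_d).  Exponential stepping on that
    grid is therefore exact for piecewise-constant inputs and
    unconditionally stable; no generic ODE solver is involved.
    """
    if not isinstance(c_out.index, pd.DatetimeIndex):
        raise ValidationError("c_out must be indexed by timestamp")
    if not c_out.index.is_monotonic_increasing or c_out.index.has_duplicates:
        raise ValidationError("c_out timestamps must be strictly increasing")
    c = c_out.to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValidationError("outdoor concentration must be >= 0")
    if c_in_initial < 0:
        raise ValidationError("initial indoor concentration must be >= 0")
    if np.isscalar(aer) or np.ndim(aer) == 0:
        a = np.full(len(c), float(aer))
    else:
        aligned = aer.reindex(c_out.index) if isinstance(aer, pd.Series) else pd.Series(
            np.asarray(aer, dtype=float), index=c_out.index
        )
        if aligned.isna().any():
            raise ValidationError("AER series does not cover the c_out grid")
        a = aligned.to_numpy(dtype=float)
    if np.any(a < 0):
        raise ValidationError("AER must be >= 0")

    dt_h = np.diff(c_out.index.to_numpy()).astype("timedelta64[s]").astype(float) / 3600.0
    loss = a + pollutant.deposition
    out = np.empty(len(c))
    out[0] = c_in_initial
    for i in range(len(c) - 1):
        # coefficients held at their value at the start of the interval
        if loss[i] > 0:
            c_ss = pollutant.penetration * a[i] * c[i] / loss[i]
            out[i + 1] = c_ss + (out[i] - c_ss) * np.exp(-loss[i] * dt_h[i])
        else:
            out[i + 1] = out[i]
    return pd.Series(out, index=c_out.index, name="c_in")


def exposure(c_out_ss, inputs: ExposureInputs):
    """Time-activity-weighted exposure E = C_out_ss (f_in F_inf + (1 − f_in)).

    Bounded between C_out_ss·F_inf (all time indoors) and C_out_ss (all
    time outdoors).
    """
    f_inf = infiltration_factor(inputs.pollutant, inputs.aer)
    atten = inputs.f_in * f_inf + (1.0 - inputs.f_in)
    out = np.asarray(c_out_ss, dtype=float) * atten
    return out if out.ndim else float(out)
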
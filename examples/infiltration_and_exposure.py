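"""Indoor infiltration and exposure from the air exchange rate.

Computes the steady-state infiltration factor of outdoor PM2.5 for a tight
and a leaky home, integrates the dynamic indoor mass balance through a
morning traffic peak, and converts the result into a time-activity-weighted
exposure.
"""

import numpy as np
import pandas as pd

from aerhome import (
    ExposureInputs,
    PollutantParams,
    dynamic_indoor,
    exposure,
    infiltration_factor,
)

pm25 = PollutantParams(penetration=0.9, deposition=1.0)

print("Steady state: fraction of outdoor PM2.5 found indoors (F_inf)")
for label, aer in (("tight (0.1 1/h)", 0.1), ("typical (0.64 1/h)", 0.64),
                   ("leaky (3.0 1/h)", 3.0)):
    print(f"  {label:>18}: F_inf = {infiltration_factor(pm25, aer):.2f}")

# a 4-hour outdoor traffic peak of 30 ug/m3 over a 10 ug/m3 background
index = pd.date_range("2012-03-01", periods=24, freq="h")
c_out = pd.Series(np.where((index.hour >= 7) & (index.hour < 11), 30.0, 10.0),
                  index=index)
tight = dynamic_indoor(c_out, 0.3, pm25, c_in_initial=2.0)
leaky = dynamic_indoor(c_out, 2.0, pm25, c_in_initial=2.0)
print("\nDynamic response to a 07:00-11:00 outdoor peak (ug/m3):")
print(f"  peak indoors, tight home (AER 0.3): {tight.max():.2f} "
      f"at {tight.idxmax():%H:%M}")
print(f"  peak indoors, leaky home (AER 2.0): {leaky.max():.2f} "
      f"at {leaky.idxmax():%H:%M}")
print("  -> the tighter envelope rises more slowly and peaks lower.")

e = exposure(10.0, ExposureInputs(f_in=0.66, pollutant=pm25, aer=0.64))
print(f"\nExposure with 66% of time indoors at home, outdoor 10 ug/m3: "
      f"{e:.2f} ug/m3")
print("  (between the fully-indoor and fully-outdoor limits; using the")
print("   outdoor value alone would overstate this person's exposure.)")
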
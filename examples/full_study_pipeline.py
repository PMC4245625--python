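"""The whole pipeline in one call: simulate, calibrate, evaluate, predict.

Runs a reduced synthetic study (60 homes, two years) end-to-end and prints
where each artefact landed plus the indoor-temperature sensitivity of the
stock-wide AER predictions.  Equivalent shell command:

    aerhome run --out-dir scratch/demo --seed 11
"""

import datetime as dt
import warnings
from pathlib import Path

import pandas as pd

from aerhome import RunConfig, run_full_study

out = Path("scratch/full_study_demo")
cfg = RunConfig(out_dir=out, seed=11, n_homes=60, end=dt.date(2011, 12, 31))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_full_study(cfg)

print("stage record counts:")
for stage, info in manifest["stages"].items():
    print(f"  {stage}: {info}")

sens = pd.read_csv(out / "tin_sensitivity.csv")
print("\nindoor-temperature sensitivity of predicted daily AER (1/h):")
print(sens.to_string(index=False))
print("  -> raising the assumed indoor temperature strengthens the stack")
print("     effect in a cool climate, nudging the median AER upward; the")
print("     spread across 20-28 C is small, supporting a constant 24 C.")

seasonal = pd.read_csv(out / "aer_summary_by_season_road.csv")
print("\nseasonal medians (1/h):")
print(seasonal.groupby("season")["median"].median().round(2).to_string())
print(f"\nall outputs and the manifest are under {out}/")
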
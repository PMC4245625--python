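"""Daily air-exchange-rate prediction for a small housing stock.

Builds two contrasting homes, generates one synthetic year of hourly
weather, and predicts daily (24-h average) AER with the leakage-only LBL
model and — on days with open windows — the LBLX extension.
"""

import datetime as dt

import pandas as pd

from aerhome import (
    Home,
    IncomeClass,
    RoadType,
    SyntheticConfig,
    generate_weather,
    leakage_area,
    predict_daily_series,
)

old_leaky = Home("old-1920", year_built=1920, floor_area=100.0, n_stories=2,
                 income_class=IncomeClass.LOW_INCOME, shelter_class=4,
                 road_type=RoadType.HTHD)
new_tight = Home("new-1995", year_built=1995, floor_area=180.0, n_stories=1,
                 income_class=IncomeClass.CONVENTIONAL, shelter_class=4,
                 road_type=RoadType.LTLD)

for h in (old_leaky, new_tight):
    print(f"{h.home_id}: effective leakage area = "
          f"{leakage_area(h) * 1e4:.0f} cm2")

weather = generate_weather(SyntheticConfig(seed=1), dt.date(2011, 1, 1),
                           dt.date(2011, 12, 31))
daily = predict_daily_series([old_leaky, new_tight], weather)

print("\nDaily AER (1/h) over one synthetic year, indoor temperature 24 C:")
for hid, sub in daily.groupby("home_id"):
    v = sub["aer_per_h"]
    print(f"  {hid}: min {v.min():.2f}  median {v.median():.2f}  "
          f"max {v.max():.2f}")
print("  -> the older, leakier envelope exchanges air faster and swings")
print("     more with weather; both peak in winter when the indoor-outdoor")
print("     temperature difference (stack effect) is largest.")

# open two windows for half a day in mild weather: LBLX adds ventilation
diary = pd.DataFrame(
    {"home_id": ["old-1920"], "date": [dt.date(2011, 6, 15)],
     "open_window_days": [1.0]}
)
june = weather[(weather.index >= "2011-06-14") & (weather.index < "2011-06-17")]
lbl = predict_daily_series([old_leaky], june, model="lbl")
lblx = predict_daily_series([old_leaky], june, model="lblx", diaries=diary)
cmp = lbl.merge(lblx, on=["home_id", "date"], suffixes=("_lbl", "_lblx"))
print("\nWindow opening on 2011-06-15 (one window-day):")
for r in cmp.itertuples(index=False):
    print(f"  {r.date}: LBL {r.aer_per_h_lbl:.2f}  LBLX {r.aer_per_h_lblx:.2f}")
print("  -> the models agree exactly on closed-window days.")
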
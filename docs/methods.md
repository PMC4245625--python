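# Methods

## Scope and assumptions

`aerhome` treats each residence as a single, well-mixed zone with no
internal resistance to airflow. Two airflow pathways are modeled: leakage
through unintentional envelope openings (LBL) and natural ventilation
through open windows (LBLX). Mechanical ventilation (outdoor-vented fans,
duct leakage) is out of scope; predictions are for homes where those
contributions are absent or small. The AER over an interval is the modeled
airflow divided by the interior volume, and daily values are
midnight-to-midnight means of hourly predictions.

## Units and coefficient convention

Internally: temperatures in °C, wind speed in m/s at the 10 m reference
height, lengths/areas in m/m², AER in 1/h. The leakage-airflow coefficient
convention is the ASHRAE residential basic model: leakage area in cm²,
airflow in L/s, stack coefficient k_s in (L/s)²·cm⁻⁴·K⁻¹ and wind
coefficient k_w in (L/s)²·cm⁻⁴·(m/s)⁻², so `AER = 3.6·Q[L/s]/V[m³]`. The
shipped k_s (by stories: 1.45/2.90/4.35 × 10⁻⁴) and k_w (by stories ×
five shelter classes) are the standard ASHRAE table values; studies with
their own coefficient sets override them via `coefficients.yaml`. File
readers declare the wind unit of their source (m/s, km/h, knots) and
convert on ingest, so one internal unit flows through the models.

The leakage-area model itself (`A_leak = NL/NF`) is kept in m² exactly as
the normalized-leakage formulation defines it; the cm² conversion happens
once, inside the airflow model.

## Leakage-area regression and age regimes

`NL = exp(β0 + β1·Y_built + β2·A_floor)` with one (β0, β1, β2) triple per
house type (low-income = household income below 125% of the poverty
guideline, vs conventional) and age regime. Homes built in or before the
cutoff year (default 1979) use field-calibrated "older" triples; newer
homes use literature-reported triples (low-income: 11.1, −5.37×10⁻³,
−4.18×10⁻³; conventional: 20.7, −1.07×10⁻², −2.20×10⁻³, with β2 per m²).
The same regression is applied to all housing kinds (detached, apartment,
townhome) — no kind-specific adjustment is attempted. Income class is a
required input; nothing is imputed. β2 confidence intervals in the older
regime cross zero, but all three coefficients are retained.

## Natural ventilation constants

Opening effectiveness C_v = 0.30, discharge coefficient C_D = 0.65, one
window opening = 0.06 m² (0.6 m × 0.1 m), lower-opening midpoint at 0.91 m,
neutral pressure level at half the building height, and
`A_nat = 0.5 × (window-days) × 0.06 m²` from the diary (windows open ×
fraction of day). In the buoyancy term the temperature difference is the
Celsius difference (identical in Kelvin) while the denominator
max{T_in, T_out} is converted to Kelvin: a Celsius denominator would blow
up unphysically near 0 °C, and the underlying orifice formula is defined on
absolute temperature. A lower-opening midpoint at or above the neutral
pressure level is rejected as out of model scope. Negative diary values
are clamped to zero with a logged warning (diaries are occupant-reported).

Quadrature combinations use `hypot`, which guarantees `hypot(q, 0) == q`;
closed-window LBLX predictions are therefore bit-identical to LBL, not
merely close.

## Indoor temperature and weather handling

For stock-wide prediction T_in is a constant 24 °C at every hour (the
median indoor temperature of instrumented homes; a sensitivity sweep over
20/24/28 °C is part of the pipeline output). For calibration, measured
per-(home, day) 24-h mean indoor temperatures are applied uniformly across
that day's hours. Wind speed is used as observed at 10 m; the shelter-class
coefficient is the only terrain adjustment.

Missing weather hours are linearly interpolated across gaps of at most 6
consecutive hours; any longer gap marks the affected day invalid
(`aer_per_h = NaN`, with the count of valid hours reported) rather than
silently dropping it — daily averages built from sparse hours would bias
the stack term. Calibration uses the alternative averaging path: 24-h mean
temperature and wind time-matched to the 24-h integrated measurements,
since sqrt(k_s|ΔT| + k_w U²) is convex in U and averaging order matters.

## Calibration

The cost is the plain sum of squared daily prediction errors over every
(home, measurement-day) pair; estimation uses the LBLX model (the
measured subset has diaries) and evaluation reports both LBLX and LBL.
Optimization is Nelder–Mead initialized at the literature triples.
Internally the exponent is reparametrized as
`z0 + z1·(Y−Ȳ)/s_Y + z2·(A−Ā)/s_A` (training-set means and spreads):
on the raw scale β0 and β1 are nearly collinear (Y_built ≈ 1900–1970),
which cripples the simplex; the standardized parametrization is
well-conditioned and maps back to (β0, β1, β2) exactly. Tolerances are
xatol 10⁻⁸ and fatol 10⁻¹⁰ with up to 5000 iterations; convergence is
confirmed by restarting a fresh simplex from the solution and requiring
the same cost within tolerance (up to 3 confirmation restarts). These
tolerances are tighter than typical defaults because the floor-area
coefficient is O(10⁻³)–O(10⁻⁴) and meaningful relative accuracy on it
demands a finely resolved optimum. No box constraints are imposed; after
a full-data fit, any calibration home whose fitted NL leaves [0.01, 10] is
flagged with a warning as a physical-plausibility guard.

The jackknife removes all days of one home per fold (the home, not the
day, is the exchangeable unit, because tracer bias is home-level) and
refits from the literature initialization each time. The point estimate is
the mean of the fold estimates; the 95% CI uses the standard jackknife
variance `(n−1)/n · Σ(θ_i − θ̄)²` with normal quantiles — the canonical
Tukey construction, adopted because the CI recipe is otherwise
unspecified. Non-converged folds are excluded from the summary with a
warning. Held-out predictions for each fold's left-out home are stored and
are the only predictions the evaluation stage consumes.

## Evaluation metrics

Relative difference ε = 100·(pred − meas)/meas (undefined and rejected for
meas ≤ 0) and absolute difference Δ = pred − meas; positive means
overestimation. ε is retained even when small measured AER makes it large —
Δ is reported alongside precisely for that case. Correlations are computed
on per-home mean pairs (each home contributes one effective point, with
equal home weights; day-count weighting after home-averaging is not
applied), Spearman on the ranks of those means, and R² is the square of
the weighted Pearson r. Quantiles everywhere use linear interpolation
between order statistics (type 7), the most common default, stated so the
numbers are reproducible. Seasons are meteorological (Dec–Feb winter,
etc.); a (home, day) counts as "open" iff its diary entry is positive,
with absent entries meaning closed.

## Indoor mass balance

The dynamic solution holds AER and C_out piecewise-constant on the input
grid (hourly in practice) and steps the exact exponential solution across
each interval — unconditionally stable and exact for piecewise-constant
coefficients, so no generic ODE machinery is involved. Defaults P = 0.9
and k_d = 1.0 1/h are the conventional PM2.5 values; the model is linear
and unit-agnostic in concentration.

## Synthetic-study generator

The generator emulates the structure of a near-road cohort study so every
stage is testable offline: a 213-home stock split 52/46/115 across the
HTHD/HTLD/LTLD road strata, built 1888–2007 (uniform), lognormal floor
areas (median 115 m², log-sd 0.32, clipped to 55–420 m²), 1–3 stories,
70% low-income, mostly shelter classes 3–5; a 24-home measured subset of
23 older homes (17 low-income, 6 conventional, built 1900–1969) plus one
1997 home, with road counts 7/5/12. Weather is an annual temperature
sinusoid (mean 9.8 °C, amplitude 14 °C, coldest mid-January) plus diurnal
cycle, AR(1) day-to-day noise and hourly jitter, with lognormal AR(1) wind
around a 3.5 m/s median — a cool-continental pattern in which the winter
indoor–outdoor gap is large and the summer gap near zero while wind varies
little by season. Window-opening probability is logistic in the daily
|T_in − T_out| (0.5 at equal temperatures, ≈ 0.15 at a 12 K gap, ≈ 2% in
deep winter), putting roughly 15% of fall/spring measurement days in the
open-window class. Measurements are LBLX-model truth times a per-home
lognormal bias (CV 0.225, the middle of the 20–25% tracer accuracy band)
times a per-day lognormal replicate error (CV 0.10, within the 5–15%
precision band); multiplicative lognormal error matches percentage-quoted
error bands and keeps AER positive. Five consecutive days per home in each
of two seasonal windows (early October, mid-April) mimic the two-season
campaign design.

What the generator does **not** emulate: real airport weather records
(fronts, storms, diurnal wind structure), occupant behaviour beyond the
temperature-coupled diary, measurement limits of detection, multizone
effects, or mechanical ventilation. Passing tests therefore demonstrate
internal correctness and statistical behaviour of the method under its own
assumptions — not field accuracy for any particular city.

## Problem sizes used in tests

The test suite runs the calibration stratum at its study size (17
low-income / 6 conventional homes × 10 measured days), the jackknife
coverage study at 200 noise replicates of the 17-home stratum, and the
prediction patterns on the full 213-home stock over three years of hourly
weather; the shared fixtures use two-year weather. These sizes keep the
whole suite around a minute while exercising every code path at realistic
scale.

## Known limitations

* Single-zone physics: no interior temperature/pressure gradients.
* The leakage regression extrapolates poorly outside the built-year and
  floor-area ranges it was fit on; the exponent is range-checked only
  against numerical overflow and the NL plausibility guard.
* The jackknife CI assumes approximate normality of the fold estimates;
  with 6-home strata the intervals are wide and fragile.
* LBLX requires diaries; in their absence the pipeline exposes LBL only,
  which slightly underestimates on open-window days.
* ε is unstable for very small measured AER by construction; use Δ there.
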
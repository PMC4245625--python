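import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aerhome import (
    IndoorTempPolicy,
    NaturalVentConfig,
    ValidationError,
    derive_volume,
    lbl_aer,
    lbl_airflow,
    lblx_aer,
    leakage_area,
    natural_stack_flow,
    natural_vent_area,
    natural_wind_flow,
    predict_daily_series,
)
from aerhome.models import daily_weather_means

CFG = NaturalVentConfig()


class TestLblAirflow:
    def test_zero_when_no_driving_force(self):
        assert lbl_airflow(0.05, 20.0, 20.0, 0.0, 1.45e-4, 1.04e-4) == 0.0

    def test_linear_in_wind_when_no_stack(self):
        q1 = lbl_airflow(0.05, 20.0, 20.0, 2.0, 1.45e-4, 1.04e-4)
        q2 = lbl_airflow(0.05, 20.0, 20.0, 4.0, 1.45e-4, 1.04e-4)
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_hand_value_500cm2(self):
        # 500 cm2, dT = 20 K, U = 4 m/s:
        # Q = 500 * sqrt(1.45e-4*20 + 1.04e-4*16) = 500 * sqrt(4.564e-3) L/s
        q = lbl_airflow(0.05, 24.0, 4.0, 4.0, 1.45e-4, 1.04e-4)
        assert q == pytest.approx(500.0 * math.sqrt(4.564e-3), rel=1e-12)
        assert q == pytest.approx(33.7787, abs=1e-4)

    def test_nonpositive_leakage_area_rejected(self):
        with pytest.raises(ValidationError):
            lbl_airflow(0.0, 24.0, 4.0, 4.0, 1.45e-4, 1.04e-4)


class TestLblAer:
    def test_flow_over_volume_conversion(self, home):
        # AER [1/h] must equal 3.6 * Q[L/s] / V[m3]
        ks, kw = 1.45e-4, 1.04e-4
        q = lbl_airflow(leakage_area(home), 24.0, 4.0, 4.0, ks, kw)
        assert lbl_aer(home, 24.0, 4.0, 4.0) == pytest.approx(
            3.6 * q / derive_volume(home), rel=1e-12
        )

    def test_lblx_never_below_lbl(self, home):
        aer_l = lbl_aer(home, 24.0, 10.0, 3.0)
        aer_x = lblx_aer(home, 24.0, 10.0, 3.0, open_window_days=1.5)
        assert aer_x >= aer_l


class TestNaturalVent:
    def test_wind_flow_zero_area(self):
        assert natural_wind_flow(0.0, 5.0, CFG) == 0.0

    def test_wind_flow_hand_value(self):
        assert natural_wind_flow(0.03, 2.0, CFG) == pytest.approx(0.018, rel=1e-12)

    def test_wind_flow_linear(self):
        assert natural_wind_flow(0.03, 1.0, CFG) == pytest.approx(
            0.5 * natural_wind_flow(0.03, 2.0, CFG), rel=1e-12
        )

    def test_stack_flow_zero_at_equal_temps(self, home):
        assert natural_stack_flow(0.03, 21.0, 21.0, home, CFG) == 0.0

    def test_stack_flow_hand_value(self, home):
        # 1 storey: H = 3.0 m, dH_NPL = 1.5 - 0.91 = 0.59 m; Kelvin denominator
        q = natural_stack_flow(0.03, 24.0, 4.0, home, CFG)
        expected = 0.65 * 0.03 * math.sqrt(2 * 9.81 * 0.59 * 20.0 / 297.15)
        assert q == pytest.approx(expected, rel=1e-12)
        assert q == pytest.approx(0.017212, abs=1e-6)

    def test_stack_flow_symmetric_in_temperatures(self, home):
        assert natural_stack_flow(0.03, 24.0, 4.0, home, CFG) == pytest.approx(
            natural_stack_flow(0.03, 4.0, 24.0, home, CFG), rel=1e-12
        )

    def test_opening_above_npl_rejected(self, home):
        cfg = NaturalVentConfig(lower_opening_midpoint=1.6)  # above H/2 = 1.5 m
        with pytest.raises(ValidationError, match="neutral pressure"):
            natural_stack_flow(0.03, 24.0, 4.0, home, cfg)

    def test_vent_area_from_diary(self):
        # two windows open all day: A_nat = 0.5 * 2 * 0.06 m2
        assert natural_vent_area(2.0, CFG) == pytest.approx(0.06)

    def test_negative_diary_clamped(self):
        assert natural_vent_area(-1.0, CFG) == 0.0


class TestLblx:
    def test_closed_windows_bit_identical_to_lbl(self, home):
        t_in, t_out, u = 24.0, 2.0, 5.0
        assert lblx_aer(home, t_in, t_out, u, 0.0) == lbl_aer(home, t_in, t_out, u)

    @given(
        owd=st.floats(0.1, 6.0),
        t_out=st.floats(-20.0, 35.0),
        u=st.floats(0.0, 15.0),
    )
    def test_quadrature_bounds(self, owd, t_out, u):
        from aerhome import Home, IncomeClass, RoadType

        home = Home("Q", 1942, 120.0, 1, IncomeClass.LOW_INCOME, 4, RoadType.LTLD)
        lbl = lbl_aer(home, 24.0, t_out, u)
        lblx = lblx_aer(home, 24.0, t_out, u, owd)
        a_nat = natural_vent_area(owd)
        q_nat = math.hypot(
            natural_wind_flow(a_nat, u), natural_stack_flow(a_nat, 24.0, t_out, home)
        )
        nat_aer = 3.6 * 1e3 * q_nat / derive_volume(home)
        assert max(lbl, nat_aer) <= lblx <= lbl + nat_aer + 1e-12


@given(
    dt1=st.floats(0.0, 30.0),
    ddt=st.floats(0.1, 20.0),
    u1=st.floats(0.0, 12.0),
    du=st.floats(0.1, 8.0),
)
def test_aer_monotone_in_driving_forces(dt1, ddt, u1, du):
    """AER strictly increases in |dT| at fixed U, and in U at fixed dT."""
    from aerhome import Home, IncomeClass, RoadType

    home = Home("M", 1942, 120.0, 1, IncomeClass.LOW_INCOME, 4, RoadType.LTLD)
    assert lbl_aer(home, 24.0, 24.0 - dt1 - ddt, 3.0) > lbl_aer(
        home, 24.0, 24.0 - dt1, 3.0
    )
    assert lbl_aer(home, 24.0, 24.0 - 10.0, u1 + du) > lbl_aer(
        home, 24.0, 24.0 - 10.0, u1
    )
    assert lblx_aer(home, 24.0, 24.0 - dt1 - ddt, 3.0, 1.0) > lblx_aer(
        home, 24.0, 24.0 - dt1, 3.0, 1.0
    )


class TestPredictDailySeries:
    def test_constant_weather_daily_equals_hourly(self, home, constant_weather):
        daily = predict_daily_series([home], constant_weather)
        expected = lbl_aer(home, 24.0, 14.0, 3.0)
        assert (daily["n_valid_hours"] == 24).all()
        assert daily["aer_per_h"].to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_empty_stock_rejected(self, constant_weather):
        with pytest.raises(ValidationError):
            predict_daily_series([], constant_weather)

    def test_short_gap_interpolated_long_gap_invalidates(self, home, constant_weather):
        w = constant_weather.copy()
        # 3-hour gap on day 2: interpolable; 8-hour gap on day 4: invalid
        w.iloc[24 + 6 : 24 + 9, w.columns.get_loc("t_out_c")] = np.nan
        w.iloc[3 * 24 + 2 : 3 * 24 + 10, w.columns.get_loc("t_out_c")] = np.nan
        daily = predict_daily_series([home], w.dropna(how="any"))
        by_date = daily.set_index("date")
        days = sorted(by_date.index)
        assert by_date.loc[days[1], "n_valid_hours"] == 24
        assert np.isfinite(by_date.loc[days[1], "aer_per_h"])
        assert by_date.loc[days[3], "n_valid_hours"] == 16
        assert np.isnan(by_date.loc[days[3], "aer_per_h"])

    def test_lblx_equals_lbl_without_diary(self, home, constant_weather):
        lbl = predict_daily_series([home], constant_weather, model="lbl")
        lblx = predict_daily_series([home], constant_weather, model="lblx")
        assert (lbl["aer_per_h"].to_numpy() == lblx["aer_per_h"].to_numpy()).all()

    def test_hourly_averaging_exceeds_daily_mean_inputs_when_wind_varies(self, home):
        # two-point wind day: sqrt(a + b u^2) is convex in u, so averaging
        # hourly AER gives more than feeding the daily-mean wind through
        index = pd.date_range("2010-06-01", periods=24, freq="h")
        u = np.where(np.arange(24) < 12, 1.0, 7.0)
        w = pd.DataFrame(
            {"t_out_c": np.full(24, 10.0), "wind_speed_ms": u}, index=index
        )
        daily = predict_daily_series([home], w)
        from_hourly = float(daily["aer_per_h"].iloc[0])
        from_daily_means = lbl_aer(home, 24.0, 10.0, 4.0)
        assert from_hourly > from_daily_means

    def test_volume_scale_invariance(self, constant_weather):
        """Doubling volume at fixed leakage area halves the AER (Q/V)."""
        from aerhome import Home, IncomeClass, RoadType

        h1 = Home("V1", 1942, 120.0, 1, IncomeClass.LOW_INCOME, 4, RoadType.LTLD,
                  volume=290.0)
        h2 = Home("V2", 1942, 120.0, 1, IncomeClass.LOW_INCOME, 4, RoadType.LTLD,
                  volume=580.0)
        d1 = predict_daily_series([h1], constant_weather)
        d2 = predict_daily_series([h2], constant_weather)
        assert d1["aer_per_h"].to_numpy() == pytest.approx(
            2.0 * d2["aer_per_h"].to_numpy(), rel=1e-12
        )


def test_daily_weather_means_complete_days_only(constant_weather):
    w = constant_weather.iloc[:-1]  # truncate the last day to 23 hours
    means = daily_weather_means(w)
    assert len(means) == 6
    assert means["t_out_c"].to_numpy() == pytest.approx(14.0)
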
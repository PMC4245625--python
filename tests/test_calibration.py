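import dataclasses
import datetime as dt
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from aerhome import (
    AgeRegime,
    CalibrationProblem,
    Home,
    IncomeClass,
    LeakageParams,
    RoadType,
    ValidationError,
    cost,
    fit_stratum,
    jackknife,
    lblx_aer,
)
from aerhome.models import daily_weather_means


def toy_problem(homes, measurements, diaries=None, **kwargs):
    index = pd.date_range("2010-10-01", periods=10 * 24, freq="h")
    rng = np.random.default_rng(1)
    weather = pd.DataFrame(
        {
            "t_out_c": 10.0 + rng.normal(0, 2, len(index)),
            "wind_speed_ms": np.exp(rng.normal(1.2, 0.3, len(index))),
        },
        index=index,
    )
    init = LeakageParams(11.1, -5.37e-3, -4.18e-3, IncomeClass.LOW_INCOME, AgeRegime.OLDER)
    return CalibrationProblem(
        homes=homes,
        measurements=measurements,
        diaries=diaries if diaries is not None else pd.DataFrame(
            columns=["home_id", "date", "open_window_days"]
        ),
        weather=weather,
        init_params=kwargs.pop("init_params", init),
        **kwargs,
    )


def make_homes(n, years=(1920, 1935, 1950), areas=(90.0, 120.0, 160.0)):
    return [
        Home(
            f"T{i}",
            years[i % len(years)],
            areas[i % len(areas)],
            1 + i % 2,
            IncomeClass.LOW_INCOME,
            4,
            RoadType.LTLD,
        )
        for i in range(n)
    ]


def forward_measurements(homes, problem_weather, params, dates):
    """Brute-force LBLX daily predictions used as noise-free measurements."""
    from aerhome import LeakageParamSet

    pset = LeakageParamSet().replaced(params)
    means = daily_weather_means(problem_weather)
    rows = []
    for h in homes:
        for d in dates:
            aer = lblx_aer(
                h, 24.0, float(means.loc[d, "t_out_c"]),
                float(means.loc[d, "wind_speed_ms"]), 0.0, param_set=pset,
            )
            rows.append({"home_id": h.home_id, "date": d, "aer_per_h": aer})
    return pd.DataFrame(rows)


TRUTH = LeakageParams(65.5, -3.40e-2, -7.33e-4, IncomeClass.LOW_INCOME, AgeRegime.OLDER)


@pytest.fixture
def noise_free_problem():
    homes = make_homes(5)
    placeholder = pd.DataFrame(
        {"home_id": [h.home_id for h in homes],
         "date": [dt.date(2010, 10, 2)] * len(homes),
         "aer_per_h": [1.0] * len(homes)}
    )
    weather = toy_problem(homes, placeholder).weather  # toy weather is seeded
    dates = [dt.date(2010, 10, 2) + dt.timedelta(days=k) for k in range(6)]
    meas = forward_measurements(homes, weather, TRUTH, dates)
    return toy_problem(homes, meas)


class TestCost:
    def test_zero_at_generating_parameters(self, noise_free_problem):
        assert cost(TRUTH, noise_free_problem) == pytest.approx(0.0, abs=1e-20)

    def test_single_record_arithmetic(self):
        homes = make_homes(1)
        meas = pd.DataFrame(
            {"home_id": ["T0"], "date": [dt.date(2010, 10, 3)], "aer_per_h": [0.6]}
        )
        p = toy_problem(homes, meas)
        pred = forward_measurements(homes, p.weather, TRUTH, [dt.date(2010, 10, 3)])
        expected = (float(pred["aer_per_h"].iloc[0]) - 0.6) ** 2
        assert cost(TRUTH, p) == pytest.approx(expected, rel=1e-12)

    def test_equals_brute_force_sum_on_three_homes(self):
        homes = make_homes(3)
        dates = [dt.date(2010, 10, 2), dt.date(2010, 10, 4)]
        p = toy_problem(
            homes,
            pd.DataFrame(
                [
                    {"home_id": h.home_id, "date": d, "aer_per_h": 0.3 + 0.1 * i}
                    for i, (h, d) in enumerate(
                        [(h, d) for h in homes for d in dates]
                    )
                ]
            ),
        )
        preds = forward_measurements(homes, p.weather, TRUTH, dates)
        merged = preds.merge(
            p.measurements, on=["home_id", "date"], suffixes=("_pred", "_meas")
        )
        brute = sum(
            (r.aer_per_h_pred - r.aer_per_h_meas) ** 2
            for r in merged.itertuples(index=False)
        )
        assert cost(TRUTH, p) == pytest.approx(brute, rel=1e-12)

    def test_uncovered_measurement_day_reported(self):
        homes = make_homes(1)
        meas = pd.DataFrame(
            {"home_id": ["T0"], "date": [dt.date(2011, 5, 1)], "aer_per_h": [0.6]}
        )
        p = toy_problem(homes, meas)
        with pytest.raises(ValidationError, match="2011, 5, 1"):
            cost(TRUTH, p)


class TestFitStratum:
    def test_recovers_generating_parameters(self, noise_free_problem):
        res = fit_stratum(noise_free_problem)
        assert res.converged
        for name in ("beta0", "beta1", "beta2"):
            fitted, true = getattr(res.params, name), getattr(TRUTH, name)
            assert abs(fitted - true) / abs(true) < 1e-4

    def test_initializing_at_optimum_is_fixed_point(self, noise_free_problem):
        p = dataclasses.replace(noise_free_problem, init_params=TRUTH)
        res = fit_stratum(p)
        assert res.j_train == pytest.approx(0.0, abs=1e-12)
        assert res.params.beta0 == pytest.approx(TRUTH.beta0, rel=1e-6)

    def test_single_home_single_day_matches_closed_form(self):
        """At J = 0 with windows closed the exponent inverts algebraically:
        beta0 = ln(measured / base) - beta1*Y - beta2*A."""
        homes = make_homes(1)
        meas = pd.DataFrame(
            {"home_id": ["T0"], "date": [dt.date(2010, 10, 3)], "aer_per_h": [0.8]}
        )
        p = toy_problem(homes, meas)
        res = fit_stratum(p)
        assert res.j_train == pytest.approx(0.0, abs=1e-14)
        d = p.design()
        beta = res.params
        closed_form_beta0 = (
            math.log(0.8 / d.base[0])
            - beta.beta1 * homes[0].year_built
            - beta.beta2 * homes[0].floor_area
        )
        assert beta.beta0 == pytest.approx(closed_form_beta0, abs=1e-6)

    def test_improves_on_initialization(self, study):
        older = [h for h in study.calibration_homes
                 if h.year_built <= 1979 and h.income_class is IncomeClass.LOW_INCOME]
        init = dataclasses.replace(
            LeakageParams(11.1, -5.37e-3, -4.18e-3, IncomeClass.LOW_INCOME,
                          AgeRegime.NEWER),
            age_regime=AgeRegime.OLDER,
        )
        p = CalibrationProblem(
            homes=older,
            measurements=study.measurements,
            diaries=study.diaries,
            weather=study.weather,
            indoor_temps=study.indoor_temps,
            init_params=init,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_stratum(p)
        assert res.j_train <= cost(init, p)

    def test_mixed_stratum_rejected(self):
        homes = make_homes(2)
        homes[1] = dataclasses.replace(homes[1], income_class=IncomeClass.CONVENTIONAL)
        with pytest.raises(ValidationError, match="income"):
            toy_problem(homes, pd.DataFrame(
                {"home_id": ["T0", "T1"], "date": [dt.date(2010, 10, 2)] * 2,
                 "aer_per_h": [1.0, 1.0]}
            ))

    def test_home_without_measurements_rejected(self):
        homes = make_homes(2)
        with pytest.raises(ValidationError, match="T1"):
            toy_problem(homes, pd.DataFrame(
                {"home_id": ["T0"], "date": [dt.date(2010, 10, 2)],
                 "aer_per_h": [1.0]}
            ))


class TestJackknife:
    def test_identical_homes_give_zero_variance(self):
        homes = [
            Home(f"S{i}", 1940, 110.0, 1, IncomeClass.LOW_INCOME, 4, RoadType.LTLD)
            for i in range(3)
        ]
        meas = pd.DataFrame(
            [
                {"home_id": h.home_id, "date": dt.date(2010, 10, 2 + k),
                 "aer_per_h": [0.7, 0.9, 0.8][k]}
                for h in homes
                for k in range(3)
            ]
        )
        jk = jackknife(toy_problem(homes, meas))
        assert jk.n_folds == 3
        betas = jk.folds[["beta0", "beta1", "beta2"]].to_numpy()
        assert np.allclose(betas, betas[0])
        assert jk.params.ci_low == pytest.approx(jk.params.ci_high, abs=1e-8)

    def test_fold_counts_match_strata(self, study):
        older = [h for h in study.calibration_homes if h.year_built <= 1979]
        for income, expected in (
            (IncomeClass.LOW_INCOME, 17),
            (IncomeClass.CONVENTIONAL, 6),
        ):
            stratum = [h for h in older if h.income_class is income]
            init = LeakageParams(
                *(11.1, -5.37e-3, -4.18e-3) if income is IncomeClass.LOW_INCOME
                else (20.7, -1.07e-2, -2.20e-3),
                house_type=income,
                age_regime=AgeRegime.OLDER,
            )
            p = CalibrationProblem(
                homes=stratum,
                measurements=study.measurements,
                diaries=study.diaries,
                weather=study.weather,
                indoor_temps=study.indoor_temps,
                init_params=init,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                jk = jackknife(p)
            assert jk.n_folds == expected
            assert len(jk.validation) == len(
                study.measurements[
                    study.measurements["home_id"].isin(h.home_id for h in stratum)
                ]
            )

    def test_held_out_home_never_enters_training(self):
        """Corrupting one home's measurements must not move the fold that
        leaves that home out."""
        homes = make_homes(4)
        dates = [dt.date(2010, 10, 2) + dt.timedelta(days=k) for k in range(4)]
        p0 = toy_problem(homes, pd.DataFrame(
            [{"home_id": h.home_id, "date": d, "aer_per_h": 1.0}
             for h in homes for d in dates]
        ))
        meas = forward_measurements(homes, p0.weather, TRUTH, dates)
        clean = jackknife(toy_problem(homes, meas))
        corrupted_meas = meas.copy()
        corrupted_meas.loc[corrupted_meas["home_id"] == "T2", "aer_per_h"] *= 7.0
        corrupted = jackknife(toy_problem(homes, corrupted_meas))
        clean_row = clean.folds.set_index("left_out_home").loc["T2"]
        corr_row = corrupted.folds.set_index("left_out_home").loc["T2"]
        for c in ("beta0", "beta1", "beta2"):
            assert clean_row[c] == pytest.approx(corr_row[c], rel=1e-9)
        other = corrupted.folds.set_index("left_out_home").loc["T0"]
        assert not np.isclose(
            other["beta0"], clean.folds.set_index("left_out_home").loc["T0", "beta0"],
            rtol=1e-6,
        )

    def test_deterministic(self, noise_free_problem):
        a = jackknife(noise_free_problem)
        b = jackknife(noise_free_problem)
        pd.testing.assert_frame_equal(a.folds, b.folds)

    def test_needs_two_homes(self):
        homes = make_homes(1)
        p = toy_problem(homes, pd.DataFrame(
            {"home_id": ["T0"], "date": [dt.date(2010, 10, 2)], "aer_per_h": [1.0]}
        ))
        with pytest.raises(ValidationError, match=">= 2"):
            jackknife(p)
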
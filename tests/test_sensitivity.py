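import numpy as np
import pandas as pd
import pytest

from itsim import (
    AnalysisConfig,
    analyze,
    fit_extended_model,
    generate_series,
    holiday_power_check,
    shifted_treatment_analysis,
    window_sweep,
)
from itsim.design import build_pretreatment_design
from itsim.model import fit_nb
from itsim.sensitivity import extended_analysis


@pytest.fixture(scope="module")
def tiny_config():
    return AnalysisConfig(seed=3, lag_order=1, n_sims=100)


class TestShiftedTreatment:
    def test_shift_zero_reproduces_baseline_exactly(self, series3, mortality_params3, tiny_config):
        base = analyze(series3, mortality_params3.calendar, tiny_config)
        table = shifted_treatment_analysis(
            series3, mortality_params3.calendar, tiny_config, shifts=[0]
        )
        assert len(table.scenarios) == 1
        for a, b in zip(table.scenarios[0].effects, base.effects):
            assert a == b

    def test_fourteen_anticipatory_scenarios(self, series3, mortality_params3, tiny_config):
        table = shifted_treatment_analysis(
            series3, mortality_params3.calendar, tiny_config, shifts=range(1, 15)
        )
        assert [s.label for s in table.scenarios] == [f"shift={k}" for k in range(1, 15)]
        assert not any(s.failed for s in table.scenarios)
        frame = table.to_frame()
        assert set(frame["scenario"]) == {f"shift={k}" for k in range(1, 15)}

    def test_scenario_carries_config_delta(self, series3, mortality_params3, tiny_config):
        table = shifted_treatment_analysis(
            series3, mortality_params3.calendar, tiny_config, shifts=[5]
        )
        assert table.scenarios[0].config_delta == {"shift_days": 5}


class TestWindowSweep:
    def test_three_windows_three_scenarios(self, series3, mortality_params3, tiny_config):
        table = window_sweep(series3, mortality_params3.calendar, tiny_config,
                             windows=(15, 30, 80))
        assert [s.label for s in table.scenarios] == ["window=15", "window=30", "window=80"]
        assert not any(s.failed for s in table.scenarios)

    def test_duplicate_window_deduplicated(self, series3, mortality_params3, tiny_config):
        table = window_sweep(series3, mortality_params3.calendar, tiny_config,
                             windows=(30, 30, 15))
        assert [s.label for s in table.scenarios] == ["window=30", "window=15"]

    def test_too_small_window_marked_failed_run_continues(self, series3, mortality_params3, tiny_config):
        table = window_sweep(series3, mortality_params3.calendar, tiny_config,
                             windows=(10, 30))
        assert table.scenarios[0].failed
        assert "window=10" in table.scenarios[0].error
        assert not table.scenarios[1].failed

    def test_effects_stable_across_windows_on_wellspecified_data(
        self, series3, mortality_params3
    ):
        cfg = AnalysisConfig(seed=4, lag_order=1, n_sims=400)
        table = window_sweep(series3, mortality_params3.calendar, cfg,
                             windows=(20, 30, 60))
        day0 = [s.effects[0].mean_diff for s in table.scenarios]
        spread = np.ptp(day0)
        width = table.scenarios[1].effects[0].ci_high - table.scenarios[1].effects[0].ci_low
        assert spread < width  # window choice moves the estimate less than its CI


class TestExtendedModel:
    def test_linear_basis_matches_baseline_on_same_rows(
        self, series3, mortality_params3, tiny_config
    ):
        base_dm = build_pretreatment_design(
            series3, mortality_params3.calendar, tiny_config, 1
        )
        base = fit_nb(base_dm)
        ext, ext_dm = fit_extended_model(
            series3, mortality_params3.calendar, tiny_config,
            spline_df=1, n_harmonics=0, lag_order=1, pretreatment="window",
        )
        assert ext_dm.n_obs == base_dm.n_obs
        # identical column space: same optimum and same trend slope
        assert ext.log_likelihood == pytest.approx(base.log_likelihood, abs=2e-4)
        assert ext.coefficients["cal_trend"] == pytest.approx(
            base.coefficients["trend"], abs=1e-4
        )
        assert ext.coefficients["lag1"] == pytest.approx(
            base.coefficients["lag1"], abs=1e-3
        )

    def test_interdistribution_span_starts_30_days_after_previous(
        self, series3, mortality_params3, tiny_config
    ):
        _, dm = fit_extended_model(
            series3, mortality_params3.calendar, tiny_config, spline_df=4,
            n_harmonics=1, lag_order=1,
        )
        years = mortality_params3.calendar.study_years
        second = dm.row_meta[dm.row_meta["year"] == years[1]]
        expected_start = mortality_params3.distribution_dates[years[0]] + pd.Timedelta(days=30)
        assert second["date"].min() == expected_start
        expected_end = mortality_params3.distribution_dates[years[1]] - pd.Timedelta(days=1)
        assert second["date"].max() == expected_end

    def test_spline_df_two_rejected(self, series3, mortality_params3, tiny_config):
        with pytest.raises(ValueError, match="spline_df"):
            fit_extended_model(series3, mortality_params3.calendar, tiny_config,
                               spline_df=2, n_harmonics=0)

    def test_planted_sinusoid_recovered(self, mortality_params3, tiny_config):
        amp, phase = 0.3, 0.7
        params = mortality_params3.replace(
            seasonal_amplitude=amp, seasonal_phase=phase, ar_coefficients=(),
        )
        series = generate_series(params, seed=21)
        model, dm = fit_extended_model(
            series, params.calendar, tiny_config, spline_df=3, n_harmonics=1,
            lag_order=1,
        )
        a = model.coefficients["sin_1"]
        b = model.coefficients["cos_1"]
        est_amp = float(np.hypot(a, b))
        # generator phase is referenced to Jan 1 of the first study year; the
        # model's harmonics to the first pretreatment day
        origin_offset = (dm.row_meta["date"].min() - series.dates[0]).days
        expected_shift = phase + 2 * np.pi * origin_offset / 365.25
        est_phase = float(np.arctan2(b, a))
        assert est_amp == pytest.approx(amp, abs=0.08)
        delta = (est_phase - expected_shift + np.pi) % (2 * np.pi) - np.pi
        assert abs(delta) < 0.3

    def test_extended_analysis_runs_downstream_pipeline(
        self, series3, mortality_params3, tiny_config
    ):
        scen = extended_analysis(series3, mortality_params3.calendar, tiny_config,
                                 spline_df=4, n_harmonics=1)
        assert not scen.failed
        assert len(scen.effects) == tiny_config.horizon_days + 1


class TestHolidayCheck:
    def test_two_holidays_two_scenarios(self, series3, mortality_params3, tiny_config):
        table = holiday_power_check(series3, ["01-01", "07-04"], tiny_config)
        assert [s.label for s in table.scenarios] == ["holiday=01-01", "holiday=07-04"]
        assert not any(s.failed for s in table.scenarios)

    def test_holiday_years_respect_window_and_horizon(self, series3, tiny_config):
        # Jan 1 of the first series year has no 30-day pretreatment history
        table = holiday_power_check(series3, ["01-01"], tiny_config)
        scen = table.scenarios[0]
        res = scen.result
        assert min(res.calendar.study_years) > min(series3.dates.year)
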
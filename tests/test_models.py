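"""Response-function shapes, stage-date simulation, and GST computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricepheno.models import (
    CultivarParams,
    ModelId,
    NonMaturingError,
    ResponseParams,
    compute_gst,
    daily_rate,
    read_cultivar_params,
    read_weather,
    simulate_stage_dates,
    write_cultivar_params,
    write_weather,
)
from ricepheno.synth import SiteClimate, generate_weather


def constant_weather(tmean: float, n_days: int = 400, start="2001-01-01") -> pd.DataFrame:
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {"date": dates, "tmin": tmean - 4.0, "tmax": tmean + 4.0}
    )


class TestDailyRate:
    def test_zero_at_and_below_base_temperature(self, schematic_params, temperature_grid):
        below = temperature_grid[temperature_grid <= 8.0]
        for params in schematic_params.values():
            assert np.all(daily_rate(below, params) == 0.0)

    def test_positive_above_base_below_ceiling(self, schematic_params, temperature_grid):
        inside = temperature_grid[(temperature_grid > 8.0) & (temperature_grid < 42.0)]
        for params in schematic_params.values():
            assert np.all(daily_rate(inside, params) > 0.0)

    def test_gdd_is_linear_above_base(self, schematic_params):
        p = schematic_params[ModelId.GDD]
        assert daily_rate(8.0, p) == 0.0
        assert daily_rate(20.0, p) == pytest.approx(12.0)

    def test_optimum_families_zero_at_and_above_ceiling(
        self, schematic_params, temperature_grid
    ):
        above = temperature_grid[temperature_grid >= 42.0]
        for m in (ModelId.BILINEAR, ModelId.BETA):
            assert np.all(daily_rate(above, schematic_params[m]) == 0.0)

    @pytest.mark.parametrize("model", [ModelId.BILINEAR, ModelId.BETA])
    def test_unique_argmax_at_optimum(self, schematic_params, temperature_grid, model):
        rates = daily_rate(temperature_grid, schematic_params[model])
        top = temperature_grid[np.argmax(rates)]
        assert top == pytest.approx(30.0)
        # unique: strictly below the peak everywhere off the optimum
        off = np.abs(temperature_grid - 30.0) > 0.5
        assert rates[off].max() < rates.max()

    @pytest.mark.parametrize("model", [ModelId.GDD, ModelId.EXPONENTIAL])
    def test_no_optimum_families_nondecreasing(
        self, schematic_params, temperature_grid, model
    ):
        rates = daily_rate(temperature_grid, schematic_params[model])
        assert np.all(np.diff(rates) >= 0.0)

    def test_non_finite_temperature_rejected(self, schematic_params):
        with pytest.raises(ValueError):
            daily_rate(np.nan, schematic_params[ModelId.GDD])

    @given(
        tb=st.floats(0, 14), span1=st.floats(1, 20), span2=st.floats(1, 20),
        tsen=st.floats(0.05, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rates_finite_nonnegative_for_valid_params(self, tb, span1, span2, tsen):
        grid = np.linspace(-5, 50, 200)
        for params in (
            ResponseParams(ModelId.GDD, tb=tb),
            ResponseParams(ModelId.EXPONENTIAL, tb=tb, tsen=tsen),
            ResponseParams(ModelId.BILINEAR, tb=tb, to=tb + span1, tc=tb + span1 + span2),
            ResponseParams(
                ModelId.BETA, tb=tb, to=tb + span1, tc=tb + span1 + span2, tsen=tsen
            ),
        ):
            r = daily_rate(grid, params)
            assert np.all(np.isfinite(r)) and np.all(r >= 0.0)


class TestResponseParamsValidation:
    def test_cardinal_order_enforced(self):
        with pytest.raises(ValueError, match="Tb < To < Tc"):
            ResponseParams(ModelId.BILINEAR, tb=30.0, to=20.0, tc=42.0)

    def test_unused_fields_rejected(self):
        with pytest.raises(ValueError, match="does not use"):
            ResponseParams(ModelId.GDD, tb=8.0, to=30.0)

    def test_tsen_must_be_positive(self):
        with pytest.raises(ValueError, match="TSEN"):
            ResponseParams(ModelId.EXPONENTIAL, tb=8.0, tsen=-0.1)


class TestSimulateStageDates:
    def test_constant_temperature_gdd_closed_form(self, schematic_params):
        # 120 units at 12 units/day -> flowering on day 10
        cp = CultivarParams("cv", schematic_params[ModelId.GDD], 120.0, 600.0)
        w = constant_weather(20.0)
        dae_f, dae_m = simulate_stage_dates(w, w["date"].iloc[5], cp)
        assert dae_f == 10
        assert dae_m == 50
        assert dae_f <= dae_m

    def test_flowering_never_after_maturity(self, schematic_cultivars):
        w = constant_weather(26.0)
        for cp in schematic_cultivars.values():
            dae_f, dae_m = simulate_stage_dates(w, w["date"].iloc[0], cp)
            assert dae_f <= dae_m

    def test_supra_optimal_warming_slows_bilinear_development(self, schematic_params):
        cp = CultivarParams("cv", schematic_params[ModelId.BILINEAR], 40.0, 70.0)
        w30, w34 = constant_weather(30.0), constant_weather(34.0)
        dae30 = simulate_stage_dates(w30, w30["date"].iloc[0], cp)
        dae34 = simulate_stage_dates(w34, w34["date"].iloc[0], cp)
        assert dae34[0] > dae30[0] and dae34[1] > dae30[1]

    def test_truncation_after_maturity_is_irrelevant(self, schematic_cultivars):
        cp = schematic_cultivars[ModelId.BETA]
        w = constant_weather(26.0, n_days=300)
        emergence = w["date"].iloc[0]
        dae = simulate_stage_dates(w, emergence, cp)
        truncated = w.iloc[: dae[1] + 1].reset_index(drop=True)
        assert simulate_stage_dates(truncated, emergence, cp) == dae

    @pytest.mark.parametrize("model", list(ModelId))
    def test_sub_optimal_warming_never_delays(self, schematic_cultivars, model):
        # a uniform +delta on a series inside (Tb, To) cannot slow development
        cp = schematic_cultivars[model]
        base = constant_weather(22.0)
        warmed = base.assign(tmin=base["tmin"] + 2.0, tmax=base["tmax"] + 2.0)
        d0 = simulate_stage_dates(base, base["date"].iloc[0], cp)
        d1 = simulate_stage_dates(warmed, warmed["date"].iloc[0], cp)
        assert d1[0] <= d0[0] and d1[1] <= d0[1]

    def test_non_maturing_error_carries_deficit(self, schematic_params):
        cp = CultivarParams("cv", schematic_params[ModelId.GDD], 120.0, 1e6)
        w = constant_weather(20.0, n_days=60)
        with pytest.raises(NonMaturingError) as err:
            simulate_stage_dates(w, w["date"].iloc[0], cp)
        assert err.value.stage == "maturity"
        assert err.value.deficit > 0


class TestComputeGST:
    def test_constant_series(self):
        w = constant_weather(25.0)
        assert compute_gst(w, w["date"].iloc[0], w["date"].iloc[100]) == 25.0

    def test_two_day_window_average(self):
        dates = pd.date_range("2001-06-01", periods=2, freq="D")
        w = pd.DataFrame({"date": dates, "tmin": [16.0, 26.0], "tmax": [24.0, 34.0]})
        assert compute_gst(w, dates[0], dates[1]) == pytest.approx(25.0)

    def test_whole_year_sinusoid_recovers_annual_mean(self):
        clim = SiteClimate("s", annual_mean=21.0, annual_amplitude=9.0)
        w = generate_weather(clim, 2001, seed=0)
        gst = compute_gst(w, w["date"].iloc[0], w["date"].iloc[-1])
        assert gst == pytest.approx(21.0, abs=1e-6)

    def test_order_enforced(self):
        w = constant_weather(25.0)
        with pytest.raises(ValueError):
            compute_gst(w, w["date"].iloc[10], w["date"].iloc[10])


class TestIO:
    def test_weather_round_trip(self, tmp_path):
        w = constant_weather(23.5, n_days=30)
        path = tmp_path / "w.csv"
        write_weather(w, path, header_comment="unit test")
        back = read_weather(path)
        pd.testing.assert_frame_equal(back, w)

    def test_weather_gap_rejected(self, tmp_path):
        w = constant_weather(23.5, n_days=30).drop(index=10)
        path = tmp_path / "w.csv"
        write_weather(w, path)
        with pytest.raises(ValueError, match="consecutive"):
            read_weather(path)

    def test_weather_tmin_above_tmax_rejected(self, tmp_path):
        w = constant_weather(23.5, n_days=5)
        w.loc[2, "tmin"] = 99.0
        path = tmp_path / "w.csv"
        write_weather(w, path)
        with pytest.raises(ValueError, match="tmin > tmax"):
            read_weather(path)

    def test_cultivar_params_round_trip(self, tmp_path, schematic_cultivars):
        path = tmp_path / "params.yaml"
        write_cultivar_params(schematic_cultivars.values(), path)
        back = read_cultivar_params(path)
        for cp in schematic_cultivars.values():
            assert back[cp.cultivar_id] == cp
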
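"""Fit metrics, the two-level auto-calibration, and validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ricepheno.calibrate import (
    _Objective,
    calibrate_cultivar,
    fit_metrics,
    validate_cultivar,
)
from ricepheno.models import CultivarParams, ModelId, ResponseParams
from ricepheno.synth import constant_regime_trials
from ricepheno.trials import Trial


class TestFitMetrics:
    def test_identity(self):
        m = fit_metrics([100, 110, 120], [100, 110, 120])
        assert (m.mad, m.nrmse) == (0.0, 0.0)
        assert m.alpha == pytest.approx(1.0)
        assert m.beta_intercept == pytest.approx(0.0)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_offset(self):
        m = fit_metrics([100, 100], [102, 102])
        assert m.mad == pytest.approx(2.0)
        assert m.nrmse == pytest.approx(2.0)
        # zero-variance observations: regression fields absent
        assert m.alpha is None and m.beta_intercept is None and m.r2 is None

    def test_hand_vector_arithmetic(self):
        # obs {90,100,110}, sim {92,101,107}: worked by hand —
        # MAD = (2+1+3)/3; RMSE = sqrt(14/3); NRMSE = 100*RMSE/100;
        # OLS sim~obs: slope = 150/200, intercept = 100 - 0.75*100,
        # r2 = 150^2/(200*114)
        m = fit_metrics([90, 100, 110], [92, 101, 107])
        assert m.mad == pytest.approx(2.0)
        assert m.nrmse == pytest.approx(100 * np.sqrt(14 / 3) / 100)
        assert m.alpha == pytest.approx(0.75)
        assert m.beta_intercept == pytest.approx(25.0)
        assert m.r2 == pytest.approx(150**2 / (200 * 114))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_metrics([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def gdd_truth():
    return CultivarParams(
        "cv", ResponseParams(ModelId.GDD, tb=8.0), 900.0, 1600.0
    )


@pytest.fixture(scope="module")
def regime_set(gdd_truth):
    temps = np.linspace(18.0, 30.0, 40)
    return constant_regime_trials(temps, gdd_truth, seed=3)


class TestCalibrateCultivar:
    def test_single_trial_is_fit_exactly(self, gdd_truth, regime_set):
        trials, weather = regime_set
        res = calibrate_cultivar(
            [trials[0]], weather, ModelId.GDD,
            fixed={"tb": 8.0}, method="grid", grid_resolution={},
        )
        # closed-form inner step: the single trial's stage dates reproduce
        assert res.metrics_flowering.mad == 0.0
        assert res.metrics_maturity.mad == 0.0
        assert res.objective_value == 0.0

    def test_noiseless_recovery_reproduces_every_trial(self, regime_set):
        trials, weather = regime_set
        res = calibrate_cultivar(trials, weather, ModelId.GDD, seed=0)
        table = validate_cultivar(res.params, trials, weather)
        assert np.all(np.abs(table["sim_flowering"] - table["obs_flowering"]) <= 1)
        assert np.all(np.abs(table["sim_maturity"] - table["obs_maturity"]) <= 1)

    def test_exponential_noiseless_recovery(self):
        truth = CultivarParams(
            "cv", ResponseParams(ModelId.EXPONENTIAL, tb=8.0, tsen=0.25), 80.0, 130.0
        )
        trials, weather = constant_regime_trials(
            np.linspace(20.0, 28.0, 40), truth, seed=5
        )
        res = calibrate_cultivar(trials, weather, ModelId.EXPONENTIAL, seed=0)
        table = validate_cultivar(res.params, trials, weather)
        assert np.all(np.abs(table["sim_flowering"] - table["obs_flowering"]) <= 1)
        assert np.all(np.abs(table["sim_maturity"] - table["obs_maturity"]) <= 1)

    def test_returned_loss_is_self_consistent(self, regime_set):
        trials, weather = regime_set
        res = calibrate_cultivar(trials, weather, ModelId.GDD, seed=0)
        obj = _Objective(trials, weather)
        assert res.objective_value == pytest.approx(
            obj.loss_for(res.params.response)[0], abs=1e-9
        )

    def test_beats_coarse_audit_grid(self, regime_set):
        trials, weather = regime_set
        res = calibrate_cultivar(trials, weather, ModelId.GDD, seed=0)
        obj = _Objective(trials, weather)
        for tb in np.arange(5.0, 15.01, 0.5):
            audit = obj.loss_for(ResponseParams(ModelId.GDD, tb=float(tb)))[0]
            assert res.objective_value <= audit + 1e-9

    def test_deterministic_given_seed(self, regime_set):
        trials, weather = regime_set
        a = calibrate_cultivar(trials, weather, ModelId.GDD, seed=42)
        b = calibrate_cultivar(trials, weather, ModelId.GDD, seed=42)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_widening_bounds_never_worsens_loss(self, regime_set):
        trials, weather = regime_set
        narrow = calibrate_cultivar(
            trials, weather, ModelId.GDD,
            bounds={"tb": (10.0, 12.0)}, method="grid",
            grid_resolution={"tb": 0.1},
        )
        wide = calibrate_cultivar(
            trials, weather, ModelId.GDD,
            bounds={"tb": (5.0, 15.0)}, method="grid",
            grid_resolution={"tb": 0.1},
        )
        assert wide.objective_value <= narrow.objective_value

    def test_infeasible_bounds_rejected(self, regime_set):
        trials, weather = regime_set
        with pytest.raises(RuntimeError, match="no feasible"):
            # base temperature above every regime: nothing ever accumulates
            calibrate_cultivar(
                trials, weather, ModelId.GDD,
                bounds={"tb": (44.0, 45.0)}, method="grid",
                grid_resolution={"tb": 0.5},
            )


class TestValidateCultivar:
    def test_validation_on_calibration_set_matches_metrics(self, regime_set):
        trials, weather = regime_set
        res = calibrate_cultivar(trials, weather, ModelId.GDD, seed=0)
        table = validate_cultivar(res.params, trials, weather)
        assert len(table) == len(trials)
        mad_m = float(np.mean(np.abs(table["sim_maturity"] - table["obs_maturity"])))
        assert mad_m == pytest.approx(res.metrics_maturity.mad)

    def test_empty_validation_set_warns(self, regime_set, caplog):
        trials, weather = regime_set
        res = calibrate_cultivar(trials, weather, ModelId.GDD, seed=0)
        with caplog.at_level("WARNING"):
            table = validate_cultivar(res.params, [], weather)
        assert table.empty
        assert "empty" in caplog.text

    def test_non_maturing_trials_flagged_and_excluded(self, regime_set, caplog):
        trials, weather = regime_set
        params = CultivarParams(
            "cv", ResponseParams(ModelId.GDD, tb=8.0), 900.0, 1.0e5
        )
        with caplog.at_level("WARNING"):
            table = validate_cultivar(params, trials, weather)
        assert table.empty
        assert "did not reach maturity" in caplog.text
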
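"""Percent bias of validated phenology predictions and its trend with ΔGST.

Percent bias is 100·(sim − obs)/obs, so positive values mean the model
simulates a longer stage duration than observed.  The warming trend of the
bias cloud is summarized by linear quantile regressions of percent bias on
ΔGST at τ = 0.025, 0.5 and 0.975 — lower, middle and upper bias envelopes.
The quantile fit minimizes the check loss exactly as a linear program; per
cultivar, an ordinary least-squares slope with a two-sided t-test flags
cultivars whose bias changes significantly with warming (P < 0.05).

The mismatch experiment reruns the whole design on synthetic truth: data
generated from a known (typically monotone, no-optimum) response family
are calibrated with each candidate family at each ΔGST threshold, and the
resulting bias trends show whether an optimum-temperature family develops
a warming bias that the matched family does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import linregress

from .calibrate import calibrate_cultivar, validate_cultivar
from .models import ModelId
from .trials import ALL, Trial, assign_delta_gst, split_experiment

__all__ = [
    "QUANTILES",
    "QuantileTrend",
    "CultivarBiasTest",
    "percent_bias",
    "quantile_trend",
    "cultivar_bias_test",
    "mismatch_experiment",
]

log = logging.getLogger(__name__)

#: Lower, middle and upper bias envelopes.
QUANTILES = (0.025, 0.5, 0.975)

#: Minimum validation points for fitting the extreme quantiles.
MIN_POINTS_EXTREME = 40


@dataclass(frozen=True)
class QuantileTrend:
    tau: float
    intercept: float  # percent bias at ΔGST = 0
    slope: float      # percent bias per °C of ΔGST


@dataclass(frozen=True)
class CultivarBiasTest:
    cultivar_id: str
    model_id: ModelId
    stage: str
    slope: float | None
    p_value: float | None
    significant: bool | None
    n: int


def percent_bias(obs, sim):
    """100 · (sim − obs) / obs; positive means overestimated duration."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed durations must be positive")
    r = 100.0 * (sim - obs) / obs
    return r if r.ndim else float(r)


def quantile_trend(x, y, tau: float) -> QuantileTrend:
    """Exact check-loss quantile regression line of ``y`` on ``x``.

    Solves min_{a,b} Σ ρ_τ(y − a − b·x) as a linear program; among
    alternate optima, the lexicographically smallest (intercept, slope)
    is returned, so the result is deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical; slope is unidentified")

    n = x.size
    # variables: a+, a-, b+, b-, u+ (n), u- (n)
    # residual identity: y_i = a + b x_i + u+_i - u-_i
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[np.arange(n), 4 + np.arange(n)] = 1.0
    A_eq[np.arange(n), 4 + n + np.arange(n)] = -1.0

    def solve(cost, extra_A=None, extra_b=None):
        res = linprog(
            cost, A_eq=A_eq, b_eq=y, A_ub=extra_A, b_ub=extra_b,
            bounds=[(0, None)] * (4 + 2 * n), method="highs",
            options={
                "primal_feasibility_tolerance": 1e-10,
                "dual_feasibility_tolerance": 1e-10,
            },
        )
        if not res.success:
            raise RuntimeError(f"quantile regression LP failed: {res.message}")
        return res

    res = solve(c)
    loss = float(res.fun)
    # lexicographic tie-break: smallest intercept, then smallest slope,
    # subject to staying at the optimal loss (tiny numerical slack)
    slack = 1e-9 * (1.0 + abs(loss))
    e_int = np.zeros(4 + 2 * n)
    e_int[0], e_int[1] = 1.0, -1.0
    res2 = solve(e_int, extra_A=c[None, :], extra_b=[loss + slack])
    a_min = float(res2.fun)
    e_slope = np.zeros(4 + 2 * n)
    e_slope[2], e_slope[3] = 1.0, -1.0
    res3 = solve(
        e_slope,
        extra_A=np.vstack([c, e_int]),
        extra_b=[loss + slack, a_min + slack],
    )
    a = float(res3.x[0] - res3.x[1])
    b = float(res3.x[2] - res3.x[3])
    return QuantileTrend(tau=float(tau), intercept=a, slope=b)


def check_loss(x, y, trend: QuantileTrend) -> float:
    """Σ ρ_τ of residuals about a fitted line (diagnostic helper)."""
    u = np.asarray(y, float) - trend.intercept - trend.slope * np.asarray(x, float)
    return float(np.sum(u * (trend.tau - (u < 0))))


def fit_quantile_trends(
    x, y, taus: Sequence[float] = QUANTILES
) -> dict[float, QuantileTrend | None]:
    """Fit the standard three envelopes; extreme quantiles need
    ≥ :data:`MIN_POINTS_EXTREME` points and are reported absent below that.

    Crossing of fitted lines inside the observed x-range (possible in
    small samples) is logged, never hidden.
    """
    x = np.asarray(x, float)
    out: dict[float, QuantileTrend | None] = {}
    for tau in taus:
        if tau not in (0.5,) and x.size < MIN_POINTS_EXTREME:
            log.warning(
                "only %d points: quantile %.3f trend reported absent "
                "(needs >= %d)", x.size, tau, MIN_POINTS_EXTREME,
            )
            out[tau] = None
            continue
        out[tau] = quantile_trend(x, y, tau)
    fitted = sorted(
        ((t, tr) for t, tr in out.items() if tr is not None), key=lambda p: p[0]
    )
    for (t1, tr1), (t2, tr2) in zip(fitted, fitted[1:]):
        for xe in (x.min(), x.max()):
            if tr1.intercept + tr1.slope * xe > tr2.intercept + tr2.slope * xe + 1e-9:
                log.warning(
                    "quantile lines tau=%.3f and tau=%.3f cross at x=%.3g",
                    t1, t2, xe,
                )
    return out


def cultivar_bias_test(
    x, y, *, cultivar_id: str = "", model_id: ModelId | str = ModelId.GDD,
    stage: str = "maturity",
) -> CultivarBiasTest:
    """OLS slope of percent bias on ΔGST with a two-sided t-test of zero.

    Needs at least 4 points and non-degenerate ΔGST; otherwise the test is
    reported absent (all statistical fields ``None``) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    model_id = ModelId(model_id)
    if x.size < 4 or np.ptp(x) == 0:
        log.warning(
            "cultivar %s (%s, %s): %d points with ΔGST range %.3g; "
            "slope test reported absent",
            cultivar_id, model_id.value, stage, x.size, float(np.ptp(x)) if x.size else 0.0,
        )
        return CultivarBiasTest(cultivar_id, model_id, stage, None, None, None, int(x.size))
    res = linregress(x, y)
    return CultivarBiasTest(
        cultivar_id=cultivar_id,
        model_id=model_id,
        stage=stage,
        slope=float(res.slope),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < 0.05),
        n=int(x.size),
    )


def bias_records(
    validation: pd.DataFrame, model_id: ModelId | str
) -> pd.DataFrame:
    """Tidy per-trial percent-bias table (both stages) from a validation
    table produced by :func:`ricepheno.calibrate.validate_cultivar`."""
    model_id = ModelId(model_id)
    frames = []
    for stage, obs_col, sim_col in (
        ("flowering", "obs_flowering", "sim_flowering"),
        ("maturity", "obs_maturity", "sim_maturity"),
    ):
        if validation.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": validation["trial_id"],
                    "cultivar_id": validation["cultivar_id"],
                    "model_id": model_id.value,
                    "stage": stage,
                    "delta_gst": validation["delta_gst"],
                    "percent_bias": percent_bias(
                        validation[obs_col], validation[sim_col]
                    ),
                }
            )
        )
    cols = ["trial_id", "cultivar_id", "model_id", "stage", "delta_gst", "percent_bias"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def mismatch_experiment(
    trials: Sequence[Trial],
    weather: Mapping[str, pd.DataFrame],
    fitted_models: Iterable[ModelId | str],
    thresholds: Sequence[float | str] = (1.0, 2.0, 3.0, ALL),
    *,
    seed: int = 0,
    calibration_kwargs: Mapping | None = None,
) -> dict:
    """Calibrate/validate every fitted family at every ΔGST threshold and
    summarize warming-bias trends.

    For numeric thresholds, only held-out (validation) trials enter the
    pooled quantile trends — they quantify predictive bias.  The ``ALL``
    control calibrates on every trial and evaluates bias on the same
    trials, mirroring the design that separates calibration-data coverage
    from model structure as the source of the trend.

    Returns a dict with keys ``records`` (tidy percent-bias table),
    ``trends`` (per model × threshold × stage × τ) and ``cultivar_tests``.
    """
    gst = assign_delta_gst(trials, weather)
    delta = {tid: g.delta_gst for tid, g in gst.items()}
    cultivars = sorted({t.cultivar_id for t in trials})
    calibration_kwargs = dict(calibration_kwargs or {})

    all_records, trend_rows, test_rows = [], [], []
    for model in fitted_models:
        model = ModelId(model)
        for threshold in thresholds:
            frames = []
            for cid in cultivars:
                exp = split_experiment(trials, gst, cid, threshold)
                cal_trials = [t for t in trials if t.trial_id in exp.calibration_ids]
                result = calibrate_cultivar(
                    cal_trials, weather, model, seed=seed, **calibration_kwargs
                )
                if threshold == ALL:
                    eval_trials = cal_trials
                else:
                    eval_trials = [
                        t for t in trials if t.trial_id in exp.validation_ids
                    ]
                table = validate_cultivar(result.params, eval_trials, weather, delta)
                frames.append(bias_records(table, model))
            records = pd.concat(frames, ignore_index=True)
            records.insert(2, "threshold", str(threshold))
            all_records.append(records)
            for stage, grp in records.groupby("stage"):
                trends = fit_quantile_trends(
                    grp["delta_gst"].to_numpy(), grp["percent_bias"].to_numpy()
                )
                for tau, tr in trends.items():
                    trend_rows.append(
                        {
                            "model_id": model.value,
                            "threshold": str(threshold),
                            "stage": stage,
                            "tau": tau,
                            "intercept": None if tr is None else tr.intercept,
                            "slope": None if tr is None else tr.slope,
                            "n": len(grp),
                        }
                    )
                for cid, cgrp in grp.groupby("cultivar_id"):
                    tst = cultivar_bias_test(
                        cgrp["delta_gst"], cgrp["percent_bias"],
                        cultivar_id=cid, model_id=model, stage=stage,
                    )
                    test_rows.append(
                        {
                            "model_id": model.value,
                            "threshold": str(threshold),
                            "stage": stage,
                            "cultivar_id": cid,
                            "slope": tst.slope,
                            "p_value": tst.p_value,
                            "significant": tst.significant,
                            "n": tst.n,
                        }
                    )
    return {
        "records": pd.concat(all_records, ignore_index=True),
        "trends": pd.DataFrame(trend_rows),
        "cultivar_tests": pd.DataFrame(test_rows),
    }
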
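"""Auto-calibration of cultivar parameters and goodness-of-fit metrics.

Calibration minimizes the summed squared day error over both stages,

    L(params) = Σ_trials (sim_flw − obs_flw)² + (sim_mat − obs_mat)²,

with a two-level search.  The outer level explores the response-shape
parameters (Tb, plus To/Tc/TSEN where the family uses them) inside bounds;
the inner level sets the two thermal requirements in closed form as the
mean accumulated development units at the observed stage dates across the
calibration trials — for a single trial this reproduces its observed dates
exactly.  The outer search is either an exhaustive grid (1–2 free
parameters) or a seeded Latin-hypercube multistart with Nelder-Mead
refinement (the default for 3–4 parameters).  Trials whose simulation never
reaches a threshold contribute a large finite penalty so the search is
steered away rather than aborted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import linregress, qmc

from .models import (
    MODEL_FIELDS,
    CultivarParams,
    ModelId,
    ResponseParams,
    daily_mean,
    daily_rate,
)
from .trials import Trial

__all__ = [
    "DEFAULT_BOUNDS",
    "FitMetrics",
    "CalibrationResult",
    "fit_metrics",
    "calibrate_cultivar",
    "validate_cultivar",
]

log = logging.getLogger(__name__)

#: Default search bounds, centred on typical rice cardinal temperatures.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tb": (5.0, 15.0),
    "to": (25.0, 35.0),
    "tc": (38.0, 46.0),
    "tsen": (0.05, 3.0),
}

#: Loss added per trial whose simulation fails to reach a stage.
NON_MATURING_PENALTY = 1.0e6


@dataclass(frozen=True)
class FitMetrics:
    """Agreement between simulated and observed stage durations.

    ``mad`` is the mean absolute deviation in days; ``nrmse`` the root
    mean square error as a percentage of the observed mean; ``alpha``,
    ``beta_intercept`` and ``r2`` come from ordinary least squares of
    simulated on observed values and are ``None`` when the observations
    are degenerate (fewer than two points or zero variance).
    """

    n: int
    mad: float
    nrmse: float
    alpha: float | None
    beta_intercept: float | None
    r2: float | None


@dataclass(frozen=True)
class CalibrationResult:
    cultivar_id: str
    model_id: ModelId
    params: CultivarParams
    objective_value: float
    metrics_flowering: FitMetrics
    metrics_maturity: FitMetrics
    converged: bool
    seed: int


def fit_metrics(obs, sim) -> FitMetrics:
    """Compute MAD, NRMSE and the sim-vs-obs regression fields."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("obs and sim must be equal-length 1-D vectors")
    err = sim - obs
    mad = float(np.mean(np.abs(err)))
    nrmse = float(100.0 * np.sqrt(np.mean(err**2)) / np.mean(obs))
    alpha = beta = r2 = None
    if obs.size >= 2 and np.ptp(obs) > 0:
        res = linregress(obs, sim)
        alpha, beta, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return FitMetrics(int(obs.size), mad, nrmse, alpha, beta, r2)


class _Objective:
    """Vectorized calibration loss over one cultivar's trial set.

    Daily mean temperatures after each trial's emergence are packed into a
    padded matrix once; every candidate evaluation is then a rate lookup,
    a cumulative sum, and two threshold crossings per trial.
    """

    def __init__(self, trials: Sequence[Trial], weather: Mapping[str, pd.DataFrame]):
        if not trials:
            raise ValueError("calibration requires at least one trial")
        self.trials = list(trials)
        self.obs_f = np.array([t.obs_flowering_dae for t in self.trials])
        self.obs_m = np.array([t.obs_maturity_dae for t in self.trials])
        spans = []
        for t in self.trials:
            w = weather[t.weather_ref]
            dates = w["date"]
            i0 = int(dates.searchsorted(t.emergence))
            if i0 >= len(dates) or dates.iloc[i0] != t.emergence:
                raise ValueError(
                    f"trial {t.trial_id}: emergence not in weather {t.weather_ref}"
                )
            tm = daily_mean(w).to_numpy()[i0 + 1:]
            if tm.size < t.obs_maturity_dae:
                raise ValueError(
                    f"trial {t.trial_id}: weather ends before observed maturity"
                )
            spans.append(tm)
        self.span = np.array([s.size for s in spans])
        width = int(self.span.max())
        # pad with an impossibly cold temperature so padded days add no units
        self.tmean = np.full((len(spans), width), -273.0)
        for i, s in enumerate(spans):
            self.tmean[i, : s.size] = s
        self.pad_mask = np.arange(width)[None, :] >= self.span[:, None]

    def thetas(self, resp: ResponseParams) -> tuple[float, float, np.ndarray]:
        # An observed stage on day d only brackets the requirement between
        # the units accumulated by day d-1 and by day d; the midpoint is the
        # unbiased closed-form choice (the upper endpoint systematically
        # overestimates theta by about half a day's units).
        cum = np.cumsum(daily_rate(self.tmean, resp), axis=1)
        rows = np.arange(len(self.trials))

        def midpoint(obs: np.ndarray) -> float:
            upper = cum[rows, obs - 1]
            lower = np.where(obs > 1, cum[rows, np.maximum(obs - 2, 0)], 0.0)
            return float(((lower + upper) / 2.0).mean())

        return midpoint(self.obs_f), midpoint(self.obs_m), cum

    def simulate(self, cum: np.ndarray, theta: float) -> np.ndarray:
        """First-crossing DAE per trial; -1 where never reached."""
        reached = cum >= theta
        reached &= ~self.pad_mask
        dae = np.argmax(reached, axis=1) + 1
        dae[~reached.any(axis=1)] = -1
        return dae

    def loss_for(self, resp: ResponseParams) -> tuple[float, float, float]:
        theta_f, theta_m, cum = self.thetas(resp)
        if theta_f <= 0 or theta_m <= theta_f:
            return NON_MATURING_PENALTY * len(self.trials), theta_f, theta_m
        loss = 0.0
        for theta, obs in ((theta_f, self.obs_f), (theta_m, self.obs_m)):
            dae = self.simulate(cum, theta)
            ok = dae > 0
            loss += float(np.sum((dae[ok] - obs[ok]) ** 2))
            # non-maturing: worst-case day error plus a fixed penalty
            loss += float(
                np.sum((self.span[~ok] - obs[~ok]) ** 2) + NON_MATURING_PENALTY * np.sum(~ok)
            )
        return loss, theta_f, theta_m


def _make_response(model_id: ModelId, values: Mapping[str, float]) -> ResponseParams | None:
    kwargs = {f: float(values[f]) for f in MODEL_FIELDS[model_id]}
    try:
        return ResponseParams(model_id=model_id, **kwargs)
    except ValueError:
        return None


def calibrate_cultivar(
    trials: Sequence[Trial],
    weather: Mapping[str, pd.DataFrame],
    model_id: ModelId | str,
    *,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | None = None,
    seed: int = 0,
    method: str = "auto",
    grid_resolution: Mapping[str, float] | None = None,
    n_starts: int = 24,
    n_refine: int = 4,
) -> CalibrationResult:
    """Fit one response family to one cultivar's calibration trials.

    Parameters
    ----------
    trials, weather
        Calibration trials and a weather lookup keyed by ``weather_ref``.
    model_id
        Response family to fit.
    bounds
        Per-parameter ``(lo, hi)`` search bounds, overriding
        :data:`DEFAULT_BOUNDS`.
    fixed
        Parameters pinned to a value and excluded from the search.
    method
        ``"grid"`` for an exhaustive grid at ``grid_resolution``,
        ``"lhs"`` for Latin-hypercube multistart with Nelder-Mead
        refinement, or ``"auto"`` (grid when ≤ 2 free parameters and a
        resolution is given, else LHS).
    seed
        Seeds the multistart sampler; identical inputs and seed give a
        bit-identical result.

    Returns
    -------
    CalibrationResult
        Best parameters, final loss, and calibration-set fit metrics.
    """
    model_id = ModelId(model_id)
    obj = _Objective(trials, weather)
    fixed = dict(fixed or {})
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    free = [f for f in MODEL_FIELDS[model_id] if f not in fixed]
    for f in free:
        if f not in bnds:
            raise ValueError(f"no bounds for free parameter {f!r}")

    def loss_vec(x: np.ndarray) -> float:
        vals = dict(fixed)
        vals.update(zip(free, x))
        for f in free:
            lo, hi = bnds[f]
            if not lo <= vals[f] <= hi:
                return NON_MATURING_PENALTY * (1 + len(obj.trials))
        resp = _make_response(model_id, vals)
        if resp is None:
            return NON_MATURING_PENALTY * (1 + len(obj.trials))
        return obj.loss_for(resp)[0]

    if method == "auto":
        method = "grid" if (grid_resolution and len(free) <= 2) else "lhs"

    converged = True
    if not free:
        best_x = np.empty(0)
        best_loss = loss_vec(best_x)
    elif method == "grid":
        if not grid_resolution:
            raise ValueError("grid method requires grid_resolution")
        axes = []
        for f in free:
            lo, hi = bnds[f]
            step = grid_resolution[f]
            n = int(round((hi - lo) / step))
            axes.append(lo + step * np.arange(n + 1))
        best_loss, best_x = np.inf, None
        for point in itertools.product(*axes):
            x = np.array(point)
            cur = loss_vec(x)
            if cur < best_loss:  # strict: first-found wins ties
                best_loss, best_x = cur, x
    elif method == "lhs":
        lo = np.array([bnds[f][0] for f in free])
        hi = np.array([bnds[f][1] for f in free])
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        starts = lo + sampler.random(n_starts) * (hi - lo)
        start_losses = np.array([loss_vec(x) for x in starts])
        order = np.argsort(start_losses, kind="stable")[: max(1, n_refine)]
        best_loss, best_x, converged = np.inf, None, False
        for idx in order:
            res = optimize.minimize(
                loss_vec,
                starts[idx],
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400 * len(free)},
            )
            if res.fun < best_loss:
                best_loss, best_x = float(res.fun), np.asarray(res.x)
                converged = bool(res.success)
    else:
        raise ValueError(f"unknown method {method!r}")

    if best_x is None or best_loss >= NON_MATURING_PENALTY:
        raise RuntimeError(
            f"calibration of {model_id.value} found no feasible parameters "
            "within bounds"
        )

    vals = dict(fixed)
    vals.update(zip(free, best_x))
    resp = _make_response(model_id, vals)
    loss, theta_f, theta_m = obj.loss_for(resp)
    params = CultivarParams(
        cultivar_id=trials[0].cultivar_id,
        response=resp,
        theta_flowering=theta_f,
        theta_maturity=theta_m,
    )
    cum = np.cumsum(daily_rate(obj.tmean, resp), axis=1)
    sim_f = obj.simulate(cum, theta_f)
    sim_m = obj.simulate(cum, theta_m)
    return CalibrationResult(
        cultivar_id=params.cultivar_id,
        model_id=model_id,
        params=params,
        objective_value=float(loss),
        metrics_flowering=fit_metrics(obj.obs_f, sim_f),
        metrics_maturity=fit_metrics(obj.obs_m, sim_m),
        converged=converged,
        seed=int(seed),
    )


def validate_cultivar(
    params: CultivarParams,
    trials: Sequence[Trial],
    weather: Mapping[str, pd.DataFrame],
    delta_gst: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Apply calibrated parameters to held-out trials without refitting.

    Returns one row per trial with simulated and observed DAE (and ΔGST
    when supplied).  Trials whose simulation never matures are excluded
    and counted in a logged warning, never silently dropped.
    """
    if not trials:
        log.warning("validate_cultivar called with an empty trial set")
        cols = ["trial_id", "cultivar_id", "delta_gst",
                "obs_flowering", "sim_flowering", "obs_maturity", "sim_maturity"]
        return pd.DataFrame(columns=cols)
    obj = _Objective(trials, weather)
    cum = np.cumsum(daily_rate(obj.tmean, params.response), axis=1)
    sim_f = obj.simulate(cum, params.theta_flowering)
    sim_m = obj.simulate(cum, params.theta_maturity)
    ok = (sim_f > 0) & (sim_m > 0)
    n_bad = int(np.sum(~ok))
    if n_bad:
        log.warning(
            "cultivar %s: %d validation trial(s) did not reach maturity and "
            "were excluded", params.cultivar_id, n_bad,
        )
    rows = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "cultivar_id": [t.cultivar_id for t in trials],
            "delta_gst": [
                np.nan if delta_gst is None else delta_gst[t.trial_id] for t in trials
            ],
            "obs_flowering": obj.obs_f,
            "sim_flowering": sim_f,
            "obs_maturity": obj.obs_m,
            "sim_maturity": sim_m,
        }
    )
    return rows[ok].reset_index(drop=True)
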
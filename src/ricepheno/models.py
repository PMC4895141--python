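"""Temperature-response functions and daily thermal-development simulation.

Four response families are supported, spanning the two structural choices
that matter for warming extrapolation: whether an optimum temperature
exists (bilinear, beta) or not (GDD, exponential), and whether the response
is linear (GDD, bilinear) or curvilinear (exponential, beta).

Development is driven by the daily mean temperature ``(tmin + tmax) / 2``.
Each day after crop emergence contributes ``daily_rate(T)`` development
units; a phenological stage is reached on the first day the running total
meets the cultivar's thermal requirement for that stage.  Rates are on
model-specific scales (GDD in °C·day, the other three normalized to a
maximum of 1), so thermal requirements are never comparable across
families — only simulated day counts are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date as Date
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ModelId",
    "ResponseParams",
    "CultivarParams",
    "NonMaturingError",
    "daily_rate",
    "accumulate",
    "simulate_stage_dates",
    "compute_gst",
    "daily_mean",
    "read_weather",
    "write_weather",
    "read_cultivar_params",
    "write_cultivar_params",
]


class ModelId(str, Enum):
    """The four temperature-response families."""

    GDD = "gdd"
    EXPONENTIAL = "exponential"
    BILINEAR = "bilinear"
    BETA = "beta"


#: Which shape parameters each family uses (beyond the base temperature).
MODEL_FIELDS: dict[ModelId, tuple[str, ...]] = {
    ModelId.GDD: ("tb",),
    ModelId.EXPONENTIAL: ("tb", "tsen"),
    ModelId.BILINEAR: ("tb", "to", "tc"),
    ModelId.BETA: ("tb", "to", "tc", "tsen"),
}


@dataclass(frozen=True)
class ResponseParams:
    """Cardinal temperatures and curvature for one response family.

    Parameters
    ----------
    model_id : ModelId
    tb : float
        Base temperature (°C); development stops at and below it.
    to : float, optional
        Optimum temperature (°C); bilinear and beta only.
    tc : float, optional
        Ceiling temperature (°C); bilinear and beta only.
    tsen : float, optional
        Dimensionless curvature; exponential and beta only.

    Fields not used by ``model_id`` must be left as ``None``.
    """

    model_id: ModelId
    tb: float
    to: float | None = None
    tc: float | None = None
    tsen: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ModelId(self.model_id))
        used = MODEL_FIELDS[self.model_id]
        for name in ("tb", "to", "tc", "tsen"):
            val = getattr(self, name)
            if name in used:
                if val is None or not math.isfinite(float(val)):
                    raise ValueError(
                        f"{self.model_id.value} model requires finite {name!r}"
                    )
            elif val is not None:
                raise ValueError(
                    f"{self.model_id.value} model does not use {name!r}"
                )
        if "to" in used and not (self.tb < self.to < self.tc):
            raise ValueError(
                f"cardinal temperatures must satisfy Tb < To < Tc, "
                f"got Tb={self.tb}, To={self.to}, Tc={self.tc}"
            )
        if "tsen" in used and not self.tsen > 0:
            raise ValueError(f"TSEN must be positive, got {self.tsen}")

    def free_fields(self) -> tuple[str, ...]:
        return MODEL_FIELDS[self.model_id]


@dataclass(frozen=True)
class CultivarParams:
    """Response parameters plus thermal requirements for one cultivar.

    ``theta_flowering`` and ``theta_maturity`` are cumulative development
    units (on the response family's own rate scale) required to reach
    flowering and physiological maturity, counted from emergence.
    """

    cultivar_id: str
    response: ResponseParams
    theta_flowering: float
    theta_maturity: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_flowering < self.theta_maturity:
            raise ValueError(
                "thermal requirements must satisfy "
                f"0 < theta_flowering < theta_maturity, got "
                f"{self.theta_flowering}, {self.theta_maturity}"
            )


class NonMaturingError(RuntimeError):
    """Accumulated development never reached a stage threshold.

    Attributes
    ----------
    stage : str
        ``"flowering"`` or ``"maturity"``.
    deficit : float
        Threshold minus the units accumulated by the end of the series.
    """

    def __init__(self, stage: str, deficit: float):
        self.stage = stage
        self.deficit = float(deficit)
        super().__init__(
            f"development never reached the {stage} threshold within the "
            f"weather span (deficit {self.deficit:.3f} units)"
        )


def daily_rate(t, params: ResponseParams):
    """Development rate at mean temperature ``t`` (°C).

    Accepts a scalar or array; returns the same shape.  All families return
    exactly 0 at and below the base temperature; bilinear and beta return 0
    at and above the ceiling and peak at the optimum.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    m = params.model_id
    if m is ModelId.GDD:
        r = np.maximum(t - params.tb, 0.0)
    elif m is ModelId.EXPONENTIAL:
        z = np.maximum(params.tsen * (t - params.tb), 0.0)
        r = -np.expm1(-z)
    elif m is ModelId.BILINEAR:
        rise = (t - params.tb) / (params.to - params.tb)
        fall = (params.tc - t) / (params.tc - params.to)
        r = np.clip(np.minimum(rise, fall), 0.0, None)
    else:  # BETA, Yin-type, normalized to 1 at To
        tb, to, tc, tsen = params.tb, params.to, params.tc, params.tsen
        q = (tc - to) / (to - tb)
        inside = (t > tb) & (t < tc)
        with np.errstate(invalid="ignore"):
            core = ((t - tb) / (to - tb)) * ((tc - t) / (tc - to)) ** q
            r = np.where(inside, np.abs(core) ** tsen, 0.0)
    return r if r.ndim else float(r)


def daily_mean(weather: pd.DataFrame) -> pd.Series:
    """Daily mean temperature series, ``(tmin + tmax) / 2``."""
    return (weather["tmin"] + weather["tmax"]) / 2.0


def accumulate(tmean: np.ndarray, params: ResponseParams) -> np.ndarray:
    """Cumulative development units over a daily mean-temperature array."""
    return np.cumsum(daily_rate(tmean, params))


def _emergence_index(weather: pd.DataFrame, emergence) -> int:
    dates = weather["date"]
    emergence = pd.Timestamp(emergence)
    idx = dates.searchsorted(emergence)
    if idx >= len(dates) or dates.iloc[idx] != emergence:
        raise ValueError(f"emergence date {emergence.date()} not in weather span")
    return int(idx)


def simulate_stage_dates(
    weather: pd.DataFrame,
    emergence,
    cultivar: CultivarParams,
) -> tuple[int, int]:
    """Simulate days after emergence (DAE) to flowering and maturity.

    Accumulation starts the day after emergence (that day is DAE 1);
    each stage's DAE is the first day on which the cumulative development
    units reach the stage's thermal requirement.

    Raises :class:`NonMaturingError` if the weather series ends before a
    threshold is crossed.
    """
    i0 = _emergence_index(weather, emergence)
    tmean = daily_mean(weather).to_numpy()[i0 + 1:]
    if tmean.size == 0:
        raise NonMaturingError("flowering", cultivar.theta_flowering)
    cum = accumulate(tmean, cultivar.response)
    return _crossings(cum, cultivar)


def _crossings(cum: np.ndarray, cultivar: CultivarParams) -> tuple[int, int]:
    total = cum[-1]
    if total < cultivar.theta_flowering:
        raise NonMaturingError("flowering", cultivar.theta_flowering - total)
    if total < cultivar.theta_maturity:
        raise NonMaturingError("maturity", cultivar.theta_maturity - total)
    dae_f = int(np.searchsorted(cum, cultivar.theta_flowering, side="left")) + 1
    dae_m = int(np.searchsorted(cum, cultivar.theta_maturity, side="left")) + 1
    return dae_f, dae_m


def compute_gst(weather: pd.DataFrame, emergence, maturity) -> float:
    """Growing season temperature: mean daily mean temperature over
    [emergence, maturity], both endpoints included."""
    emergence = pd.Timestamp(emergence)
    maturity = pd.Timestamp(maturity)
    if not emergence < maturity:
        raise ValueError("emergence must precede maturity")
    i0 = _emergence_index(weather, emergence)
    i1 = _emergence_index(weather, maturity)
    window = daily_mean(weather).to_numpy()[i0: i1 + 1]
    n_expected = (maturity - emergence).days + 1
    if window.size != n_expected:
        raise ValueError("weather series has missing days inside the GST window")
    return float(window.mean())


# ---------------------------------------------------------------------------
# I/O

def read_weather(path) -> pd.DataFrame:
    """Read a daily weather file (columns ``date,tmin,tmax``, ISO dates).

    Validates ``tmin <= tmax`` and strictly increasing, gap-free dates.
    """
    df = pd.read_csv(path, comment="#")
    required = {"date", "tmin", "tmax"}
    if not required.issubset(df.columns):
        raise ValueError(f"weather file {path} must have columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    bad = df.index[df["tmin"] > df["tmax"]]
    if len(bad):
        raise ValueError(f"tmin > tmax at rows {list(bad[:5])} in {path}")
    deltas = df["date"].diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError(f"dates must be consecutive calendar days in {path}")
    return df[["date", "tmin", "tmax"]]


def write_weather(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


def _params_to_dict(cp: CultivarParams) -> dict:
    d = {"model": cp.response.model_id.value, "tb": cp.response.tb}
    for name in ("to", "tc", "tsen"):
        val = getattr(cp.response, name)
        if val is not None:
            d[name] = val
    d["theta_flowering"] = cp.theta_flowering
    d["theta_maturity"] = cp.theta_maturity
    return d


def _params_from_dict(cultivar_id: str, d: dict) -> CultivarParams:
    resp = ResponseParams(
        model_id=ModelId(d["model"]),
        tb=float(d["tb"]),
        to=None if d.get("to") is None else float(d["to"]),
        tc=None if d.get("tc") is None else float(d["tc"]),
        tsen=None if d.get("tsen") is None else float(d["tsen"]),
    )
    return CultivarParams(
        cultivar_id=cultivar_id,
        response=resp,
        theta_flowering=float(d["theta_flowering"]),
        theta_maturity=float(d["theta_maturity"]),
    )


def write_cultivar_params(params: Iterable[CultivarParams], path) -> None:
    """Write cultivar parameter blocks as flat key-value YAML."""
    doc = {cp.cultivar_id: _params_to_dict(cp) for cp in params}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_cultivar_params(path) -> dict[str, CultivarParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {cid: _params_from_dict(cid, d) for cid, d in doc.items()}
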
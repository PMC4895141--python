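"""Synthetic weather and trial generation with known phenology truth.

Real multi-site rice trial networks span a wide range of growing-season
temperatures (GSTs) because sites differ in climate and sowing dates vary
within sites.  The generator reproduces that structure at configurable
scale: a ladder of site climates (sinusoidal seasonal cycle plus AR(1)
day-to-day noise) spaced so each cultivar's trials realize a target GST
span, emergence dates drawn within a window, and observed stage dates
produced by a *known* response model with optional rounded Gaussian
observation noise.  Because the generating parameters are recorded, every
downstream stage — calibration, validation, bias trends — can be tested
against ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    CultivarParams,
    NonMaturingError,
    daily_mean,
    simulate_stage_dates,
    write_cultivar_params,
    write_weather,
)
from .trials import Trial, assign_delta_gst, write_trials

__all__ = [
    "SiteClimate",
    "TrialDesign",
    "SyntheticDataset",
    "generate_weather",
    "generate_trials",
    "climate_ladder",
    "constant_regime_trials",
]

#: Day of year at which the seasonal sinusoid crosses its annual mean
#: rising — places the warm peak in mid-July (northern-hemisphere style).
_PHASE_DOY = 105


@dataclass(frozen=True)
class SiteClimate:
    """Parameters of one synthetic station's daily temperature process."""

    site_id: str
    annual_mean: float       # °C
    annual_amplitude: float  # °C, half peak-to-trough of the seasonal cycle
    diurnal_range: float = 8.0   # °C, tmax − tmin
    noise_sd: float = 0.0        # °C, marginal SD of the AR(1) anomaly
    ar1: float = 0.0             # lag-1 autocorrelation of the anomaly

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or not self.diurnal_range > 0:
            raise ValueError("noise_sd must be >= 0 and diurnal_range > 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class TrialDesign:
    """Shape of a synthetic multi-cultivar trial set."""

    n_cultivars: int = 19
    trials_per_cultivar: tuple[int, int] = (14, 260)
    target_gst_span: float = 5.0          # °C, per-cultivar ΔGST span
    emergence_window: tuple[int, int] = (120, 160)  # day-of-year range
    obs_noise_sd: float = 0.0             # days, stage-date observation noise
    gst_span_tolerance: float = 0.5       # °C, acceptance band on the span
    seed: int = 0


@dataclass
class SyntheticDataset:
    trials: list[Trial]
    weather: dict[str, pd.DataFrame]
    truth: dict[str, CultivarParams]
    design: TrialDesign
    climates: list[SiteClimate]

    def write(self, out_dir) -> None:
        """Emit trials.csv, weather/<ref>.csv and truth.yaml."""
        out = Path(out_dir)
        (out / "weather").mkdir(parents=True, exist_ok=True)
        write_trials(self.trials, out / "trials.csv")
        for ref, w in self.weather.items():
            write_weather(w, out / "weather" / f"{ref}.csv")
        write_cultivar_params(self.truth.values(), out / "truth.yaml")
        meta = {
            "seed": self.design.seed,
            "obs_noise_sd": self.design.obs_noise_sd,
            "target_gst_span": self.design.target_gst_span,
            "climates": [vars(c) | {"site_id": c.site_id} for c in self.climates],
        }
        with open(out / "truth_meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def generate_weather(
    climate: SiteClimate, year: int, seed: int, n_days: int | None = None
) -> pd.DataFrame:
    """One calendar year of daily tmin/tmax for a site.

    Daily mean = annual_mean + amplitude·sin(2π(doy − phase)/n) + AR(1)
    anomaly; tmin/tmax sit symmetrically about the mean.  Deterministic
    given (climate, year, seed).
    """
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(dates) if n_days is None else n_days
    dates = dates[:n]
    doy = np.arange(1, n + 1, dtype=float)
    seasonal = climate.annual_mean + climate.annual_amplitude * np.sin(
        2 * np.pi * (doy - _PHASE_DOY) / n
    )
    anomaly = np.zeros(n)
    if climate.noise_sd > 0:
        rng = np.random.default_rng(seed)
        innov_sd = climate.noise_sd * np.sqrt(1.0 - climate.ar1**2)
        e = rng.normal(0.0, innov_sd, size=n)
        anomaly[0] = rng.normal(0.0, climate.noise_sd)
        for i in range(1, n):
            anomaly[i] = climate.ar1 * anomaly[i - 1] + e[i]
    mean = seasonal + anomaly
    half = climate.diurnal_range / 2.0
    return pd.DataFrame({"date": dates, "tmin": mean - half, "tmax": mean + half})


def climate_ladder(
    n_sites: int,
    mean_range: tuple[float, float] = (16.0, 26.0),
    amplitude: float = 9.0,
    diurnal_range: float = 8.0,
    noise_sd: float = 0.0,
    ar1: float = 0.0,
) -> list[SiteClimate]:
    """Evenly spaced site climates from coolest to warmest annual mean."""
    means = np.linspace(mean_range[0], mean_range[1], n_sites)
    return [
        SiteClimate(
            site_id=f"S{i:02d}",
            annual_mean=float(m),
            annual_amplitude=amplitude,
            diurnal_range=diurnal_range,
            noise_sd=noise_sd,
            ar1=ar1,
        )
        for i, m in enumerate(means)
    ]


def constant_regime_trials(
    temps,
    truth: CultivarParams,
    *,
    seed: int = 0,
    emergence_window: tuple[int, int] = (100, 140),
    obs_noise_sd: float = 0.0,
) -> tuple[list[Trial], dict[str, pd.DataFrame]]:
    """One trial per constant-temperature regime (growth-chamber style).

    Each regime holds the daily mean at one value from ``temps`` all year
    (diurnal range still applies), isolating the temperature response from
    seasonal dynamics; emergence days are drawn from ``emergence_window``.
    Returns the trials and their weather lookup.
    """
    rng = np.random.default_rng(seed)
    trials, weather = [], {}
    for i, temp in enumerate(np.asarray(temps, dtype=float)):
        clim = SiteClimate(site_id=f"R{i:03d}", annual_mean=float(temp),
                           annual_amplitude=0.0)
        ref = f"R{i:03d}_2001"
        weather[ref] = generate_weather(clim, 2001, seed=seed)
        doy = int(rng.integers(emergence_window[0], emergence_window[1] + 1))
        emergence = weather[ref]["date"].iloc[doy - 1]
        dae_f, dae_m = simulate_stage_dates(weather[ref], emergence, truth)
        if obs_noise_sd > 0:
            dae_f = max(1, int(round(dae_f + rng.normal(0, obs_noise_sd))))
            dae_m = max(dae_f + 1, int(round(dae_m + rng.normal(0, obs_noise_sd))))
        trials.append(
            Trial(
                trial_id=f"r{i:03d}",
                cultivar_id=truth.cultivar_id,
                site_id=clim.site_id,
                year=2001,
                emergence=emergence,
                obs_flowering_dae=dae_f,
                obs_maturity_dae=dae_m,
                weather_ref=ref,
            )
        )
    return trials, weather


def generate_trials(
    design: TrialDesign,
    true_params: dict[str, CultivarParams],
    climates: list[SiteClimate],
) -> SyntheticDataset:
    """Generate a full trial set from known truth.

    Each cultivar's trials are spread across the whole climate ladder and
    the emergence window, so its realized GST range covers the design's
    target span; a cultivar whose realized ΔGST span misses the target by
    more than ``gst_span_tolerance`` raises before anything is written.
    Observed DAE = truth simulation + independent rounded Gaussian noise
    per stage (flooring at one day between stages to keep records valid).
    """
    if len(true_params) != design.n_cultivars:
        raise ValueError(
            f"design asks for {design.n_cultivars} cultivars but "
            f"{len(true_params)} parameter sets were given"
        )
    rng = np.random.default_rng(design.seed)
    year0 = 2001
    weather: dict[str, pd.DataFrame] = {}

    def site_year_weather(clim: SiteClimate, year: int) -> str:
        ref = f"{clim.site_id}_{year}"
        if ref not in weather:
            # deterministic per-series seed independent of generation order
            wseed = zlib.crc32(
                f"{clim.site_id}:{year}:{design.seed}".encode()
            ) & 0x7FFFFFFF
            weather[ref] = generate_weather(clim, year, seed=wseed)
        return ref

    trials: list[Trial] = []
    lo, hi = design.trials_per_cultivar
    e_lo, e_hi = design.emergence_window
    for ci, (cid, params) in enumerate(sorted(true_params.items())):
        n_trials = int(rng.integers(lo, hi + 1))
        # cycle sites coolest→warmest, advancing the year on each wrap, so
        # the ladder (hence the GST span) is fully covered regardless of
        # n_trials and (cultivar, site, year) stays unique
        site_idx = np.resize(np.arange(len(climates)), n_trials)
        for k in range(n_trials):
            clim = climates[site_idx[k]]
            year = year0 + k // len(climates)
            ref = site_year_weather(clim, year)
            w = weather[ref]
            doy = int(rng.integers(e_lo, e_hi + 1))
            emergence = w["date"].iloc[doy - 1]
            try:
                dae_f, dae_m = simulate_stage_dates(w, emergence, params)
            except NonMaturingError as exc:
                raise ValueError(
                    f"cultivar {cid} does not mature at site {clim.site_id} "
                    f"with emergence day {doy}: {exc}"
                ) from exc
            if design.obs_noise_sd > 0:
                dae_f = int(round(dae_f + rng.normal(0, design.obs_noise_sd)))
                dae_m = int(round(dae_m + rng.normal(0, design.obs_noise_sd)))
                dae_f = max(dae_f, 1)
                dae_m = max(dae_m, dae_f + 1)
            trials.append(
                Trial(
                    trial_id=f"{cid}-{k:03d}",
                    cultivar_id=cid,
                    site_id=clim.site_id,
                    year=year,
                    emergence=emergence,
                    obs_flowering_dae=dae_f,
                    obs_maturity_dae=dae_m,
                    weather_ref=ref,
                )
            )

    gst = assign_delta_gst(trials, weather)
    for cid in true_params:
        spans = [g.delta_gst for g in gst.values() if g.cultivar_id == cid]
        realized = max(spans)
        if abs(realized - design.target_gst_span) > design.gst_span_tolerance:
            raise ValueError(
                f"cultivar {cid}: realized ΔGST span {realized:.2f} °C is "
                f"outside {design.target_gst_span} ± "
                f"{design.gst_span_tolerance} °C; adjust the climate ladder"
            )
    return SyntheticDataset(trials, weather, dict(true_params), design, climates)
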
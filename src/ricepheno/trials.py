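"""Trial records, growing-season temperature (GST) construction, and
calibration/validation splitting.

A *trial* is one cultivar × site × year record carrying the emergence date
and the observed days after emergence (DAE) to flowering and maturity.
Within each cultivar group, ΔGST is each trial's GST minus the coolest
trial's GST, so the coolest trial of every cultivar sits at ΔGST = 0.
Calibration experiments keep the trials with ΔGST at or below a threshold
(1, 2 or 3 °C) for calibration and hold the warmer remainder out for
validation; the ``ALL`` pseudo-threshold uses every trial for calibration
and is the control design that tests whether bias trends stem from
calibration-data coverage rather than model structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import compute_gst

__all__ = [
    "Trial",
    "TrialGST",
    "CalibrationExperiment",
    "ALL",
    "load_trials",
    "write_trials",
    "assign_delta_gst",
    "split_experiment",
]

log = logging.getLogger(__name__)

#: Sentinel threshold: calibrate on every trial, validate on none.
ALL = "all"

TRIAL_COLUMNS = [
    "trial_id",
    "cultivar_id",
    "site_id",
    "year",
    "emergence_date",
    "flowering_dae",
    "maturity_dae",
    "weather_ref",
]


@dataclass(frozen=True)
class Trial:
    """One cultivar × site × year phenology record."""

    trial_id: str
    cultivar_id: str
    site_id: str
    year: int
    emergence: pd.Timestamp
    obs_flowering_dae: int
    obs_maturity_dae: int
    weather_ref: str
    # pass-through stages present in station records but unused here
    transplanting: pd.Timestamp | None = None
    panicle_initiation: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not 0 < self.obs_flowering_dae < self.obs_maturity_dae:
            raise ValueError(
                f"trial {self.trial_id}: need 0 < flowering DAE "
                f"({self.obs_flowering_dae}) < maturity DAE "
                f"({self.obs_maturity_dae})"
            )

    @property
    def maturity_date(self) -> pd.Timestamp:
        return self.emergence + timedelta(days=self.obs_maturity_dae)


@dataclass(frozen=True)
class TrialGST:
    trial_id: str
    cultivar_id: str
    gst: float
    delta_gst: float


@dataclass(frozen=True)
class CalibrationExperiment:
    """A ΔGST-threshold split of one cultivar's trials."""

    cultivar_id: str
    threshold: float | str
    calibration_ids: frozenset[str]
    validation_ids: frozenset[str]


def _check_unique(trials: Sequence[Trial]) -> None:
    seen: dict[tuple, str] = {}
    for t in trials:
        key = (t.cultivar_id, t.site_id, t.year)
        if key in seen:
            raise ValueError(
                f"duplicate cultivar/site/year {key}: trials "
                f"{seen[key]!r} and {t.trial_id!r}"
            )
        seen[key] = t.trial_id
    ids = [t.trial_id for t in trials]
    if len(set(ids)) != len(ids):
        raise ValueError("trial_id values must be unique")


def load_trials(path) -> list[Trial]:
    """Load trials from a delimited text file; enforce record invariants.

    Violations are reported with the 1-based data row number and the
    offending trial id.
    """
    df = pd.read_csv(path, comment="#", dtype={"trial_id": str, "site_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file {path} missing columns {sorted(missing)}")
    trials, errors = [], []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            trials.append(
                Trial(
                    trial_id=str(row.trial_id),
                    cultivar_id=str(row.cultivar_id),
                    site_id=str(row.site_id),
                    year=int(row.year),
                    emergence=pd.Timestamp(row.emergence_date),
                    obs_flowering_dae=int(row.flowering_dae),
                    obs_maturity_dae=int(row.maturity_dae),
                    weather_ref=str(row.weather_ref),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise ValueError(f"invalid trials in {path}:\n" + "\n".join(errors))
    _check_unique(trials)
    return trials


def write_trials(trials: Iterable[Trial], path, header_comment: str | None = None) -> None:
    """Write trials in the same dialect :func:`load_trials` reads."""
    rows = [
        {
            "trial_id": t.trial_id,
            "cultivar_id": t.cultivar_id,
            "site_id": t.site_id,
            "year": t.year,
            "emergence_date": t.emergence.strftime("%Y-%m-%d"),
            "flowering_dae": t.obs_flowering_dae,
            "maturity_dae": t.obs_maturity_dae,
            "weather_ref": t.weather_ref,
        }
        for t in trials
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def assign_delta_gst(
    trials: Sequence[Trial],
    weather: Mapping[str, pd.DataFrame],
) -> dict[str, TrialGST]:
    """Compute GST (over the observed emergence→maturity window) and ΔGST.

    ΔGST is relative to the minimum GST among the same cultivar's trials,
    so each cultivar has at least one trial at exactly 0.
    """
    gst_by_trial: dict[str, float] = {}
    for t in trials:
        w = weather[t.weather_ref]
        gst_by_trial[t.trial_id] = compute_gst(w, t.emergence, t.maturity_date)
    out: dict[str, TrialGST] = {}
    by_cultivar: dict[str, list[Trial]] = {}
    for t in trials:
        by_cultivar.setdefault(t.cultivar_id, []).append(t)
    for cid, group in by_cultivar.items():
        if len(group) == 1:
            log.warning("cultivar %s has a single trial; ΔGST set to 0", cid)
        gmin = min(gst_by_trial[t.trial_id] for t in group)
        for t in group:
            g = gst_by_trial[t.trial_id]
            out[t.trial_id] = TrialGST(t.trial_id, cid, g, g - gmin)
    return out


def split_experiment(
    trials: Sequence[Trial],
    gst: Mapping[str, TrialGST],
    cultivar_id: str,
    threshold: float | str,
) -> CalibrationExperiment:
    """Partition one cultivar's trials into calibration and validation sets.

    ``threshold`` is 1, 2 or 3 (°C, inclusive: boundary trials calibrate)
    or :data:`ALL` for the all-data control with an empty validation set.
    """
    group = [t for t in trials if t.cultivar_id == cultivar_id]
    if not group:
        raise ValueError(f"no trials for cultivar {cultivar_id!r}")
    if isinstance(threshold, str):
        if threshold.lower() != ALL:
            raise ValueError(f"threshold must be numeric or {ALL!r}, got {threshold!r}")
        cal = frozenset(t.trial_id for t in group)
        return CalibrationExperiment(cultivar_id, ALL, cal, frozenset())
    cal = frozenset(
        t.trial_id for t in group if gst[t.trial_id].delta_gst <= threshold
    )
    val = frozenset(t.trial_id for t in group) - cal
    if not cal:
        raise ValueError(
            f"cultivar {cultivar_id}: no trials with ΔGST <= {threshold} °C; "
            "use a larger threshold"
        )
    if not val:
        log.warning(
            "cultivar %s: all trials fall at or below ΔGST %s °C; "
            "validation set is empty", cultivar_id, threshold,
        )
    return CalibrationExperiment(cultivar_id, float(threshold), cal, val)
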
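"""Raw lab events -> per-patient resampled matrices on a days-before-death axis.

The canonical time axis puts death at day 0 and counts into the past;
calendar-stamped inputs are aligned once at ingest against a per-patient
death date.  Preprocessing then applies three rules, in order:

1. same-day duplicates: only the first test of a (patient, day, parameter)
   is kept;
2. coverage: a parameter is retained only if observed in more than a given
   fraction of patients (default: more than half), and patients lacking any
   event for a retained parameter are flagged for exclusion;
3. resampling: each patient's irregular series is smoothed onto an integer
   daily grid with a moving average (default window 5 days, centered);
   grid cells whose window contains no raw event stay masked (NaN).

No values are imputed anywhere; downstream boosted-tree models route
missing values natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "align_to_death",
    "dedup_first_per_day",
    "coverage_filter",
    "resample_moving_average",
    "resample_cohort",
    "CohortMatrices",
]

EVENT_COLUMNS = ["patient_id", "days_before_death", "parameter", "value"]


def _check_events(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")
    if len(events) == 0:
        raise ValueError("empty event table")


def align_to_death(events: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """Convert calendar-stamped events to the days-before-death axis.

    ``events`` needs columns patient_id, timestamp, parameter, value;
    ``deaths`` needs patient_id, death_date.  Events after death are dropped.
    """
    ev = events.merge(deaths[["patient_id", "death_date"]], on="patient_id",
                      how="inner")
    stamp = pd.to_datetime(ev["timestamp"])
    death = pd.to_datetime(ev["death_date"])
    ev["days_before_death"] = (death.dt.normalize() - stamp.dt.normalize()).dt.days
    ev = ev[ev["days_before_death"] >= 0]
    out = ev[["patient_id", "timestamp", "days_before_death", "parameter",
              "value"]].copy()
    return out.reset_index(drop=True)


def dedup_first_per_day(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only the first test per (patient, day, parameter).

    "First" follows the ``timestamp`` column when present, else the stable
    input row order (a warning is issued for untimestamped ties).
    """
    _check_events(events)
    keys = ["patient_id", "days_before_death", "parameter"]
    if "timestamp" in events.columns:
        order = pd.to_datetime(events["timestamp"])
        ev = events.assign(_order=order).sort_values(
            keys + ["_order"], kind="stable")
        out = ev.drop_duplicates(keys, keep="first").drop(columns="_order")
    else:
        if events.duplicated(keys).any():
            warnings.warn(
                "same-day duplicate tests without timestamps: keeping first "
                "by input order", stacklevel=2)
        out = events.drop_duplicates(keys, keep="first")
    return out.reset_index(drop=True)


def coverage_filter(
    events: pd.DataFrame, min_patient_fraction: float = 0.5
) -> tuple[list[str], list[str]]:
    """Select parameters tested in more than ``min_patient_fraction`` of patients.

    Returns ``(kept_parameters, excluded_patients)`` where the excluded
    patients are those lacking any event for at least one retained parameter
    (the follow-on exclusion rule).  The coverage inequality is strict:
    a parameter seen in exactly half the patients is dropped at the default.
    """
    _check_events(events)
    n_patients = events["patient_id"].nunique()
    cover = events.groupby("parameter")["patient_id"].nunique()
    kept = sorted(cover.index[cover / n_patients > min_patient_fraction])
    if not kept:
        return [], []
    counts = (events[events["parameter"].isin(kept)]
              .groupby("patient_id")["parameter"].nunique())
    all_ids = pd.Index(events["patient_id"].unique())
    excluded = sorted(all_ids[counts.reindex(all_ids, fill_value=0) < len(kept)])
    return kept, excluded


@dataclass
class CohortMatrices:
    """Resampled per-patient grids: (patient, day) x parameter, NaN = masked.

    ``values`` carries a MultiIndex (patient_id, day) over a dense day grid
    0..t_max shared by all patients; columns are parameters.
    """

    values: pd.DataFrame
    window_days: int
    align: str

    @property
    def patients(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)

    @property
    def t_max(self) -> int:
        return int(self.values.index.get_level_values(1).max())

    def day_frame(self, t: int) -> pd.DataFrame:
        """All patients' feature vectors at day ``t`` (rows = patients)."""
        if not 0 <= t <= self.t_max:
            raise ValueError(f"day {t} outside grid [0, {self.t_max}]")
        return self.values.xs(t, level=1)

    def day_vector(self, patient_id: str, t: int) -> pd.Series:
        """One patient's feature vector at day ``t``; NaN marks missing."""
        if not 0 <= t <= self.t_max:
            raise ValueError(f"day {t} outside grid [0, {self.t_max}]")
        return self.values.loc[(patient_id, t)]

    def missing_fraction(self, t: int) -> pd.Series:
        """Per-parameter fraction of patients masked at day ``t``."""
        return self.day_frame(t).isna().mean()

    def to_tidy(self) -> pd.DataFrame:
        tidy = (self.values.stack(future_stack=True)
                .rename("value").reset_index())
        tidy.columns = ["patient_id", "day", "parameter", "value"]
        tidy["observed"] = tidy["value"].notna()
        return tidy

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, window_days: int = 5,
                  align: str = "centered") -> "CohortMatrices":
        wide = tidy.pivot_table(index=["patient_id", "day"],
                                columns="parameter", values="value",
                                aggfunc="first")
        wide.columns.name = None
        # fully-masked days drop out of the pivot; restore the dense grid
        patients = tidy["patient_id"].unique()
        full = pd.MultiIndex.from_product(
            [patients, np.arange(int(tidy["day"].max()) + 1)],
            names=["patient_id", "day"])
        wide = wide.reindex(full)
        return cls(values=wide.sort_index(), window_days=window_days,
                   align=align)


def _windowed_mean(grid: np.ndarray, window_days: int, align: str) -> np.ndarray:
    """Moving average along axis 1 of a (patients, days, params) grid.

    NaNs are skipped; cells whose window holds no observation stay NaN.
    ``centered`` averages days [t-w//2, t+w//2]; ``trailing`` averages
    [t, t+w-1] in days before death, i.e. uses only information at least
    ``t`` days before death.  Windows truncate at the grid edges.
    """
    n, days, p = grid.shape
    obs = ~np.isnan(grid)
    vals = np.where(obs, grid, 0.0)
    csum = np.concatenate([np.zeros((n, 1, p)), np.cumsum(vals, axis=1)], axis=1)
    ccnt = np.concatenate([np.zeros((n, 1, p), dtype=int),
                           np.cumsum(obs, axis=1)], axis=1)
    t = np.arange(days)
    if align == "centered":
        half = window_days // 2
        lo, hi = t - half, t + half
    elif align == "trailing":
        lo, hi = t, t + window_days - 1
    else:
        raise ValueError("align must be 'centered' or 'trailing'")
    lo = np.clip(lo, 0, days - 1)
    hi = np.clip(hi, 0, days - 1)
    wsum = csum[:, hi + 1, :] - csum[:, lo, :]
    wcnt = ccnt[:, hi + 1, :] - ccnt[:, lo, :]
    with np.errstate(invalid="ignore"):
        out = np.where(wcnt > 0, wsum / np.maximum(wcnt, 1), np.nan)
    return out


def resample_cohort(
    events: pd.DataFrame,
    window_days: int = 5,
    t_max: int | None = None,
    align: str = "centered",
    parameters: list[str] | None = None,
) -> CohortMatrices:
    """Resample deduplicated events for every patient onto a daily grid.

    The estimate at day ``t`` is the arithmetic mean of raw values whose day
    falls in the smoothing window around ``t``; empty windows are masked.
    """
    _check_events(events)
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if parameters is not None:
        events = events[events["parameter"].isin(parameters)]
        if len(events) == 0:
            raise ValueError("no events left after parameter selection")
    if t_max is None:
        t_max = int(events["days_before_death"].max())

    events = events[events["days_before_death"] <= t_max]
    patients = np.sort(events["patient_id"].unique())
    params = (list(parameters) if parameters is not None
              else sorted(events["parameter"].unique()))
    p_idx = {pid: i for i, pid in enumerate(patients)}
    f_idx = {f: j for j, f in enumerate(params)}

    grid = np.full((len(patients), t_max + 1, len(params)), np.nan)
    rows = events["patient_id"].map(p_idx).to_numpy()
    days = events["days_before_death"].to_numpy(dtype=int)
    cols = events["parameter"].map(f_idx).to_numpy()
    grid[rows, days, cols] = events["value"].to_numpy(dtype=float)

    smoothed = _windowed_mean(grid, window_days, align)
    index = pd.MultiIndex.from_product(
        [patients, np.arange(t_max + 1)], names=["patient_id", "day"])
    values = pd.DataFrame(smoothed.reshape(-1, len(params)),
                          index=index, columns=params)
    return CohortMatrices(values=values, window_days=window_days, align=align)


def resample_moving_average(
    patient_events: pd.DataFrame,
    window_days: int = 5,
    t_max: int | None = None,
    align: str = "centered",
) -> pd.DataFrame:
    """Single-patient convenience wrapper around :func:`resample_cohort`.

    Returns a (day x parameter) frame indexed 0..t_max, NaN where masked.
    """
    if patient_events["patient_id"].nunique() != 1:
        raise ValueError("expected events for exactly one patient")
    mats = resample_cohort(patient_events, window_days=window_days,
                           t_max=t_max, align=align)
    pid = mats.patients[0]
    return mats.values.loc[pid]
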
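"""Participant-day measure extraction.

Converts per-burst state calls and EMA survey responses into the analysis
table: one row per participant-day with

* sleep duration — length of the longest contiguous run of observations
  predicted *not physically active*, starting after 21:00 of the prior
  evening (the run breaks on any active observation or on a timestamp gap
  larger than the gap tolerance);
* nighttime stillness — fraction of observations predicted *still* inside
  the participant's median late-evening still window;
* daytime activity — fraction of observations predicted *physically
  active* inside the participant's median active window (between the
  typical wake time, the median end of nightly not-active runs, and the
  typical rest time, the median start of the following night's run);
* time covariates (day of study, ordinal weekday Monday=0..Sunday=6) and
  daily mean mood and energy.

Conventions: run duration is last-minus-first observation time, so a
single-observation run has duration 0 (no unobserved time is invented);
medians over an even number of days take the lower order statistic, which
keeps windows on observed minute marks; the night starting at 21:00 of
day d-1 belongs to day d. Participants need at least 14 complete days
(>= 1 survey response and >= 1 valid burst) to be included. Behavior
measures are z-scored within participant; time covariates are scaled to
[0, 1] (day by n_days-1, weekday by 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._timebase import DAY_MIN, anchor_epoch_s, weekday_of_day

logger = logging.getLogger(__name__)

#: runs break on gaps longer than this multiple of the observation interval
GAP_FACTOR = 1.5
#: minimum complete days for cohort inclusion
MIN_COMPLETE_DAYS = 14


@dataclass
class PersonWindow:
    """A participant's typical daily window on the minutes-since-21:00 axis.

    Still windows satisfy 0 <= start < end <= 1440. Active windows span the
    typical wake time to the typical rest time of the *following* evening,
    so their end may lie beyond 1440 (up to 2880); the day's observations
    naturally extend into that span on the absolute axis.
    """

    participant_id: str
    kind: str  # "still" | "active"
    start_min: float
    end_min: float


def contiguous_runs(
    minutes: np.ndarray, ok: np.ndarray, gap_tolerance_min: float
) -> list[tuple[int, int]]:
    """Index ranges [i0, i1] of maximal runs where ``ok`` holds throughout.

    A run breaks on any observation with ``ok`` false or on a gap between
    consecutive observations exceeding ``gap_tolerance_min``.
    """
    runs = []
    i = 0
    n = len(minutes)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and (minutes[j + 1] - minutes[j]) <= gap_tolerance_min:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def longest_run(
    minutes: np.ndarray, ok: np.ndarray, gap_tolerance_min: float
) -> tuple[float, float] | None:
    """(start, end) minutes of the longest run; ties go to the earliest."""
    best = None
    best_dur = -1.0
    for i0, i1 in contiguous_runs(minutes, ok, gap_tolerance_min):
        dur = minutes[i1] - minutes[i0]
        if dur > best_dur:
            best = (float(minutes[i0]), float(minutes[i1]))
            best_dur = dur
    return best


def longest_nonactive_run(
    minutes: np.ndarray, is_active: np.ndarray, gap_tolerance_min: float
) -> tuple[float, float, float] | None:
    """Longest not-physically-active run in one night window.

    Returns (start_min, end_min, duration_hours) or None when the window
    holds no observations.
    """
    if len(minutes) == 0:
        return None
    run = longest_run(np.asarray(minutes, float), ~np.asarray(is_active, bool), gap_tolerance_min)
    if run is None:
        return None
    return run[0], run[1], (run[1] - run[0]) / 60.0


def lower_median(values) -> float:
    """Order statistic at ceil(n/2): the lower median for even n."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("lower_median of empty sequence")
    return float(arr[(arr.size - 1) // 2])


def median_window(day_runs: dict[int, tuple[float, float]], kind: str, participant_id: str = "") -> PersonWindow:
    """Median window over per-day runs given on the within-day minute axis.

    ``kind='still'``: window = (median run start, median run end).
    ``kind='active'``: window = (median run end, 1440 + median run start),
    i.e. typical wake to the typical rest time of the following evening.
    """
    if not day_runs:
        raise ValueError("no runs found on any day")
    starts = [s for s, _ in day_runs.values()]
    ends = [e for _, e in day_runs.values()]
    if kind == "still":
        return PersonWindow(participant_id, "still", lower_median(starts), lower_median(ends))
    if kind == "active":
        return PersonWindow(
            participant_id, "active", lower_median(ends), DAY_MIN + lower_median(starts)
        )
    raise ValueError(f"unknown window kind {kind!r}")


def fraction_in_window(
    minutes: np.ndarray, flags: np.ndarray, window: PersonWindow
) -> float:
    """Fraction of observations inside [start, end] with the flag set.

    Returns NaN when the window contains no observations (measure missing
    for that day).
    """
    minutes = np.asarray(minutes, dtype=float)
    sel = (minutes >= window.start_min) & (minutes <= window.end_min)
    if not sel.any():
        return float("nan")
    return float(np.asarray(flags, bool)[sel].mean())


def daily_wellbeing(ema: pd.DataFrame, start_date: str) -> pd.DataFrame:
    """Average all of a calendar day's survey responses into daily levels."""
    if ema.empty:
        return pd.DataFrame(columns=["participant_id", "day", "mood", "energy", "n_responses"])
    df = ema.copy()
    dates = pd.to_datetime(df["t_unix_s"], unit="s").dt.normalize()
    df["day"] = (dates - pd.Timestamp(start_date)).dt.days
    out = (
        df.groupby(["participant_id", "day"])
        .agg(mood=("mood", "mean"), energy=("energy", "mean"), n_responses=("mood", "size"))
        .reset_index()
    )
    return out


def _zscore(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        logger.warning("constant measure within participant; standardized column set to 0")
        return pd.Series(np.where(values.notna(), 0.0, np.nan), index=values.index)
    return (values - values.mean()) / sd


def build_analysis_table(
    states: pd.DataFrame,
    ema: pd.DataFrame,
    *,
    start_date: str,
    n_days: int,
    obs_interval_min: int = 5,
    gap_factor: float = GAP_FACTOR,
    min_complete_days: int = MIN_COMPLETE_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """Join state calls and surveys into the standardized analysis table.

    Returns the table (complete participant-days of included participants,
    raw and standardized columns) and an inclusion report. Participants
    with fewer than ``min_complete_days`` complete days are dropped.
    """
    if states.empty:
        raise ValueError("empty cohort: no state calls")
    gap_tol = gap_factor * obs_interval_min
    epoch0 = anchor_epoch_s(start_date)
    if "missing" in states.columns:
        states = states[~states["missing"].astype(bool)]

    rows = []
    excluded = {}
    pids = sorted(states["participant_id"].unique())
    wb = daily_wellbeing(ema, start_date)
    for pid in pids:
        sub = states[states["participant_id"] == pid].sort_values("t_unix_s")
        m_abs = (sub["t_unix_s"].to_numpy(dtype=float) - epoch0) / 60.0
        act = sub["is_active"].to_numpy(dtype=bool)
        still = sub["is_still"].to_numpy(dtype=bool)
        day_idx = np.floor(m_abs / DAY_MIN).astype(int)

        sleep_runs: dict[int, tuple[float, float]] = {}
        still_runs: dict[int, tuple[float, float]] = {}
        sleep_h: dict[int, float] = {}
        n_obs: dict[int, int] = {}
        for d in range(n_days):
            sel = day_idx == d
            n_obs[d] = int(sel.sum())
            mm = m_abs[sel] - d * DAY_MIN
            res = longest_nonactive_run(mm, act[sel], gap_tol)
            if res is not None:
                sleep_runs[d] = (res[0], res[1])
                sleep_h[d] = res[2]
            srun = longest_run(mm, still[sel], gap_tol) if sel.any() else None
            if srun is not None:
                still_runs[d] = srun

        still_win = median_window(still_runs, "still", pid) if still_runs else None
        active_win = median_window(sleep_runs, "active", pid) if sleep_runs else None

        wb_p = wb[wb["participant_id"] == pid].set_index("day")
        for d in range(n_days):
            sel = day_idx == d
            mm = m_abs[sel] - d * DAY_MIN
            stillness = (
                fraction_in_window(mm, still[sel], still_win) if still_win else float("nan")
            )
            if active_win is not None:
                sel_ext = (m_abs >= d * DAY_MIN + active_win.start_min) & (
                    m_abs <= d * DAY_MIN + active_win.end_min
                )
                activity = float(act[sel_ext].mean()) if sel_ext.any() else float("nan")
            else:
                activity = float("nan")
            n_resp = int(wb_p.loc[d, "n_responses"]) if d in wb_p.index else 0
            rows.append(
                {
                    "participant_id": pid,
                    "day": d,
                    "day_of_study": d,
                    "weekday": weekday_of_day(start_date, d),
                    "sleep_duration": sleep_h.get(d, float("nan")),
                    "daytime_activity": activity,
                    "nighttime_stillness": stillness,
                    "mood": float(wb_p.loc[d, "mood"]) if d in wb_p.index else float("nan"),
                    "energy": float(wb_p.loc[d, "energy"]) if d in wb_p.index else float("nan"),
                    "n_responses": n_resp,
                    "n_observations": n_obs[d],
                }
            )

    table = pd.DataFrame(rows)
    table["complete"] = (table["n_responses"] >= 1) & (table["n_observations"] >= 1)
    counts = table.groupby("participant_id")["complete"].sum()
    included_ids = counts[counts >= min_complete_days].index
    for pid, c in counts.items():
        if pid not in included_ids:
            excluded[pid] = f"only {int(c)} complete days (< {min_complete_days})"

    table = table[table["participant_id"].isin(included_ids) & table["complete"]].copy()
    table = table.drop(columns=["complete"])

    for raw, z in (
        ("sleep_duration", "sleep_z"),
        ("daytime_activity", "activity_z"),
        ("nighttime_stillness", "stillness_z"),
    ):
        table[z] = table.groupby("participant_id")[raw].transform(_zscore)
    table["day_s"] = table["day_of_study"] / max(n_days - 1, 1)
    table["weekday_s"] = table["weekday"] / 6.0

    report = {
        "participants_total": len(pids),
        "participants_included": int(len(included_ids)),
        "participants_excluded": int(len(pids) - len(included_ids)),
        "excluded": excluded,
        "rows": int(len(table)),
        "min_complete_days": min_complete_days,
    }
    return table.reset_index(drop=True), report
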
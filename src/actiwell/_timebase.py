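"""Shared clock conventions for night-anchored analysis.

All nightly logic runs on a "minutes since 21:00" axis so that nights never
wrap midnight: the axis for study day ``d`` starts at 21:00 on the calendar
evening before day ``d`` and spans 1440 minutes. The night that starts on
that evening belongs to day ``d`` (sleep precedes the day's mood report).
"""

from __future__ import annotations

import pandas as pd

#: minutes in one day
DAY_MIN = 1440
#: clock minute of the nightly anchor (21:00)
NIGHT_ANCHOR_CLOCK_MIN = 21 * 60
#: offset from the anchor (21:00) to the following midnight
ANCHOR_TO_MIDNIGHT_MIN = DAY_MIN - NIGHT_ANCHOR_CLOCK_MIN  # 180


def anchor_epoch_s(start_date: str) -> float:
    """Unix seconds of 21:00 on the evening before study day 0."""
    ts = pd.Timestamp(start_date)
    return float((ts - pd.Timedelta(minutes=ANCHOR_TO_MIDNIGHT_MIN)).timestamp())


def axis_minutes(t_unix_s, start_date: str):
    """Map unix timestamps to minutes on the night-anchored study axis."""
    return (pd.Series(t_unix_s, dtype=float) - anchor_epoch_s(start_date)) / 60.0


def clock_to_axis_min(day: int, clock_min: float) -> float:
    """Absolute axis minute of a clock time (minutes since midnight) on study day ``day``."""
    return day * DAY_MIN + ANCHOR_TO_MIDNIGHT_MIN + clock_min


def weekday_of_day(start_date: str, day: int) -> int:
    """Ordinal weekday, Monday=0 .. Sunday=6, of study day ``day``."""
    return int((pd.Timestamp(start_date).dayofweek + day) % 7)
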
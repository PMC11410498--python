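"""Diurnality index with milking-anchored day/night windows, and the
milking-start deviation covariate.

"Day" is the span between the end of morning milking and the start of evening
milking (roughly 7-9 h in a twice-daily parlor routine); "night" runs from
the end of evening milking to the start of the next morning milking.  The
milking intervals themselves belong to neither window.  Because milking times
drift (and their clock labels shift at daylight-saving transitions), each
day's boundaries use the sliding mean of the milking times over the 7-day
window centered on that day, computed on the UTC timeline.

The diurnality index contrasts duration-normalized activity *rates* (day and
night have unequal lengths):

    DI = (R_day - R_night) / (R_day + R_night),
    R = total motion index in window / window hours,

so DI = 1 is fully diurnal, -1 fully nocturnal, and 0 means equal rates.

Milking times were held on the clock across daylight-saving changes, so the
UTC milking time steps by an hour twice a year; herds adapt to that long-term
shift, and what carries information is the *short-term* deviation: for each
day, deviation = (that day's milking start) - (mean start over that day and
the following 6 days), in minutes, separately for morning and evening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_io import ActivitySeries, MilkingSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "DIRecord",
    "sliding_day_night",
    "diurnality_index",
    "milking_deviation",
]


@dataclass
class DIRecord:
    """Diurnality index of one cow-day."""

    cow_id: str
    day: pd.Timestamp
    di: float
    day_window: tuple[pd.Timestamp, pd.Timestamp]
    night_window: tuple[pd.Timestamp, pd.Timestamp]
    day_hours: float
    night_hours: float


def _minutes_of_day(col: pd.Series) -> pd.Series:
    """Milking time as minutes since that row's UTC midnight (can exceed 1440
    if a milking crosses midnight, keeping the sliding mean well-defined)."""
    midnights = col.dt.normalize()
    return (col - midnights).dt.total_seconds() / 60.0 + (
        (midnights - midnights.index).dt.total_seconds() / 60.0
    )


def sliding_day_night(
    schedule: MilkingSchedule, window_days: int = 7
) -> pd.DataFrame:
    """Per-day day/night windows from centered sliding-mean milking times.

    For each day with a complete centered window (the day and its 3 neighbors
    on each side, for the default 7), the day window runs from the smoothed
    morning-milking end to the smoothed evening-milking start, and the night
    window from the smoothed evening end to the *next* day's smoothed morning
    start.  Days without full coverage (edges, schedule gaps) are skipped with
    a log entry.  Returns a frame indexed by day with columns ``day_start,
    day_end, night_start, night_end, day_hours, night_hours``.
    """
    sched = schedule.data.sort_index()
    days = sched.index
    # express each milking time as minutes from its own day's UTC midnight
    mins = pd.DataFrame(
        {c: _minutes_of_day(sched[c]) for c in MilkingSchedule.COLUMNS}, index=days
    )
    half = window_days // 2
    smooth = mins.rolling(window=window_days, center=True, min_periods=window_days).mean()

    # centered window must exist AND span exactly window_days calendar days
    # (a schedule gap inside the rolling window disqualifies the day)
    day_ns = days.asi8
    ns_day = 86_400_000_000_000
    gap_ok = np.zeros(len(days), dtype=bool)
    for i in range(half, len(days) - half):
        gap_ok[i] = (day_ns[i + half] - day_ns[i - half]) == (window_days - 1) * ns_day

    rows = []
    for i, day in enumerate(days):
        if not gap_ok[i] or smooth.iloc[i].isna().any():
            logger.debug("sliding_day_night: %s skipped (incomplete window)", day.date())
            continue
        nxt = day + pd.Timedelta(days=1)
        if nxt not in smooth.index or smooth.loc[nxt].isna().any():
            continue
        day_start = day + pd.Timedelta(minutes=float(smooth.iloc[i]["morning_end"]))
        day_end = day + pd.Timedelta(minutes=float(smooth.iloc[i]["evening_start"]))
        night_start = day + pd.Timedelta(minutes=float(smooth.iloc[i]["evening_end"]))
        night_end = nxt + pd.Timedelta(minutes=float(smooth.loc[nxt]["morning_start"]))
        rows.append(
            dict(
                day=day,
                day_start=day_start,
                day_end=day_end,
                night_start=night_start,
                night_end=night_end,
                day_hours=(day_end - day_start).total_seconds() / 3600.0,
                night_hours=(night_end - night_start).total_seconds() / 3600.0,
            )
        )
    return pd.DataFrame(rows).set_index("day") if rows else pd.DataFrame(
        columns=["day_start", "day_end", "night_start", "night_end",
                 "day_hours", "night_hours"]
    )


def diurnality_index(
    series: ActivitySeries, windows: pd.DataFrame
) -> pd.DataFrame:
    """Diurnality index per cow-day.

    ``windows`` comes from :func:`sliding_day_night`.  A day is evaluated only
    when the series fully covers both its day and night windows (every
    expected bin present); days where both rates are zero are skipped with a
    warning (DI undefined).  Returns a tidy frame with one row per retained
    cow-day.
    """
    data = series.data
    bw = pd.Timedelta(minutes=series.bin_width)
    rows = []
    for day, w in windows.iterrows():
        vals = []
        covered = True
        for start, end in ((w.day_start, w.day_end), (w.night_start, w.night_end)):
            sel = data[(data.index >= start) & (data.index + bw <= end)]
            expected = int((end - start) // bw)
            if len(sel) < expected - 1:  # tolerate one boundary bin
                covered = False
                break
            vals.append(float(sel["motion_index"].sum()))
        if not covered:
            logger.debug("cow %s: DI day %s skipped (windows not covered)",
                         series.cow_id, day.date())
            continue
        r_day = vals[0] / w.day_hours
        r_night = vals[1] / w.night_hours
        if r_day + r_night == 0.0:
            logger.warning("cow %s: DI undefined on %s (no activity)",
                           series.cow_id, day.date())
            continue
        rows.append(
            dict(
                cow_id=series.cow_id,
                day=day,
                di=(r_day - r_night) / (r_day + r_night),
                day_hours=w.day_hours,
                night_hours=w.night_hours,
                rate_day=r_day,
                rate_night=r_night,
            )
        )
    return pd.DataFrame(
        rows, columns=["cow_id", "day", "di", "day_hours", "night_hours",
                       "rate_day", "rate_night"]
    )


def milking_deviation(schedule: MilkingSchedule, span: int = 7) -> pd.DataFrame:
    """Short-term milking-start deviation per day (minutes, signed).

    deviation(d) = start(d) - mean(start(d), ..., start(d + span - 1)),
    computed separately for morning and evening starts on the UTC timeline.
    Days whose forward window is incomplete get a missing value (logged).
    """
    sched = schedule.data.sort_index()
    days = sched.index
    out = pd.DataFrame(index=days)
    day_ns = days.asi8
    ns_day = 86_400_000_000_000
    fwd_ok = np.zeros(len(days), dtype=bool)
    for i in range(len(days) - span + 1):
        fwd_ok[i] = (day_ns[i + span - 1] - day_ns[i]) == (span - 1) * ns_day
    for label, col in (("morning", "morning_start"), ("evening", "evening_start")):
        m = _minutes_of_day(sched[col])
        baseline = m.iloc[::-1].rolling(span, min_periods=span).mean().iloc[::-1]
        dev = (m - baseline).to_numpy()
        dev[~fwd_ok] = np.nan
        out[f"deviation_{label}"] = dev
    n_miss = int(out["deviation_morning"].isna().sum())
    if n_miss:
        logger.info("milking_deviation: %d day(s) without a complete forward window",
                    n_miss)
    return out
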
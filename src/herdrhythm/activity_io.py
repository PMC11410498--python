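"""Reading, validation, timezone normalization, cleaning, and resampling of
minute-level cow activity data and the milking/management schedule.

The raw material is what a leg-mounted 3-axis accelerometer exports per cow:
one row per minute with a step count and a motion index (MI, a nonnegative
summary of acceleration magnitude).  Analysis happens on a single UTC
timeline; local CET/CEST timestamps (including daylight-saving transitions)
are converted first, and all "days" downstream are civil days on the UTC
axis.

Cleaning rules:

* any civil day touched by a zero-run (in either steps or MI) strictly longer
  than 12 h is excluded — such runs indicate a sensor that stopped recording;
* the first and last calendar day of a recording are excluded (device was
  mounted/removed mid-day), as are days with fewer than the expected number
  of bins;
* after cleaning, data are resampled to 15-min bins by summation.

Every exclusion is logged with cow id, day, and the rule that fired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("NOC", "DTC", "WDC")
PARITIES = ("primiparous", "multiparous")

#: minutes in a civil day
_DAY_MIN = 1440


@dataclass
class ActivitySeries:
    """One cow's activity record on a uniform time grid.

    ``data`` is indexed by tz-aware timestamps (bin start) and carries
    ``motion_index`` (float, >= 0) and ``steps`` (int, >= 0) columns.
    """

    cow_id: str
    data: pd.DataFrame
    bin_width: int = 1  # minutes
    is_cleaned: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            return
        if idx.tz is None:
            raise ValueError(f"cow {self.cow_id}: timestamps must be tz-aware")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            dup = idx[idx.duplicated()]
            first = dup[0] if len(dup) else idx[np.argmin(np.diff(idx.asi8)) + 1]
            raise ValueError(
                f"cow {self.cow_id}: non-monotone or duplicate timestamps "
                f"(first offender {first})"
            )
        if (self.data["motion_index"] < 0).any() or (self.data["steps"] < 0).any():
            raise ValueError(f"cow {self.cow_id}: negative activity values")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def days(self) -> pd.DatetimeIndex:
        """Unique civil days (midnight timestamps) present, on the current timeline."""
        return self.data.index.normalize().unique()

    def is_uniform(self) -> bool:
        if len(self.data) < 2:
            return True
        deltas = np.diff(self.data.index.asi8)
        return bool((deltas == self.bin_width * 60_000_000_000).all())


@dataclass
class MilkingSchedule:
    """Herd-level milking times, one row per calendar day.

    ``data`` is indexed by day (normalized tz-aware midnight) with tz-aware
    timestamp columns ``morning_start``, ``morning_end``, ``evening_start``,
    ``evening_end``; within each day they must be strictly increasing.
    """

    data: pd.DataFrame

    COLUMNS = ("morning_start", "morning_end", "evening_start", "evening_end")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"milking schedule missing column {col!r}")
        d = self.data
        ordered = (
            (d["morning_start"] < d["morning_end"])
            & (d["morning_end"] < d["evening_start"])
            & (d["evening_start"] < d["evening_end"])
        )
        if not ordered.all():
            bad = d.index[~ordered][0]
            raise ValueError(f"milking times out of order on {bad}")


@dataclass
class CowMeta:
    """Per-cow metadata: herd, treatment group, parity, calving, estrus days."""

    cow_id: str
    herd: str
    treatment: str
    parity: str
    lactation_number: int
    calving_date: date
    estrus_dates: tuple[date, ...] = ()
    health_excluded: bool = False

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.parity not in PARITIES:
            raise ValueError(f"unknown parity {self.parity!r}")
        if self.lactation_number < 1:
            raise ValueError("lactation_number must be >= 1")


# ---------------------------------------------------------------------------
# readers


def read_activity(path: str | Path, tz: str | None = None) -> list[ActivitySeries]:
    """Read a delimited activity table into per-cow :class:`ActivitySeries`.

    The file must have a header with columns ``cow_id``, ``timestamp``,
    ``steps``, ``motion_index``.  Timestamps are ISO-8601; if they carry no
    UTC offset they are localized to ``tz``.  A file holding a single cow
    yields a one-element list.  Malformed rows are dropped with a warning
    naming their line numbers; duplicate or non-monotone timestamps raise.
    """
    df = pd.read_csv(path)
    required = {"cow_id", "timestamp", "steps", "motion_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna() | df["steps"].isna() | df["motion_index"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning(
            "%s: dropping %d malformed row(s) at line(s) %s",
            path, int(bad.sum()), lines[:10],
        )
        df = df[~bad]
        ts = ts[~bad]
    if ts.dt.tz is None:  # pragma: no cover - utc=True always yields tz-aware
        ts = ts.dt.tz_localize(tz)
    elif tz is not None:
        ts = ts.dt.tz_convert(tz)

    out: list[ActivitySeries] = []
    for cow_id, sub in df.assign(_ts=ts).groupby("cow_id", sort=True):
        data = pd.DataFrame(
            {
                "motion_index": sub["motion_index"].to_numpy(float),
                "steps": sub["steps"].to_numpy(int),
            },
            index=pd.DatetimeIndex(sub["_ts"], name="timestamp"),
        )
        bw = 1
        if len(data) > 1:
            bw = int(np.median(np.diff(data.index.asi8)) / 60_000_000_000) or 1
        out.append(ActivitySeries(cow_id=str(cow_id), data=data, bin_width=bw))
    return out


def read_schedule(path: str | Path, tz: str | None = None) -> MilkingSchedule:
    """Read the milking schedule CSV (columns: day + the four milking times)."""
    df = pd.read_csv(path)
    for col in MilkingSchedule.COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        t = pd.to_datetime(df[col], utc=True, format="ISO8601")
        df[col] = t.dt.tz_convert(tz) if tz else t
    df.index = df[list(MilkingSchedule.COLUMNS)[0]].dt.normalize().rename("day")
    return MilkingSchedule(df[list(MilkingSchedule.COLUMNS)])


def read_metadata(path: str | Path) -> list[CowMeta]:
    """Read per-cow metadata CSV; ``estrus_dates`` is a ';'-separated list."""
    df = pd.read_csv(path, dtype={"cow_id": str, "herd": str})
    metas = []
    for _, row in df.iterrows():
        raw = row.get("estrus_dates", "")
        estrus = ()
        if isinstance(raw, str) and raw.strip():
            estrus = tuple(date.fromisoformat(s) for s in raw.split(";"))
        metas.append(
            CowMeta(
                cow_id=str(row["cow_id"]),
                herd=str(row["herd"]),
                treatment=row["treatment"],
                parity=row["parity"],
                lactation_number=int(row["lactation_number"]),
                calving_date=date.fromisoformat(str(row["calving_date"])),
                estrus_dates=estrus,
                health_excluded=bool(row.get("health_excluded", False)),
            )
        )
    return metas


# ---------------------------------------------------------------------------
# timezone normalization


def convert_to_gmt(
    series: ActivitySeries, schedule: MilkingSchedule
) -> tuple[ActivitySeries, MilkingSchedule]:
    """Convert activity and schedule to a single UTC timeline.

    A continuously logging device produces one sample per UTC minute, so
    daylight-saving transitions neither duplicate nor drop minutes here; only
    the labels change.
    """
    data = series.data.copy()
    data.index = data.index.tz_convert("UTC")
    sched = schedule.data.copy()
    for col in MilkingSchedule.COLUMNS:
        sched[col] = sched[col].dt.tz_convert("UTC")
    sched.index = sched["morning_start"].dt.normalize().rename("day")
    return (
        replace(series, data=data),
        MilkingSchedule(sched),
    )


# ---------------------------------------------------------------------------
# cleaning


def _zero_run_days(
    data: pd.DataFrame, bin_width: int, max_hours: float
) -> set[pd.Timestamp]:
    """Civil days touched by a zero-run strictly longer than ``max_hours``.

    A run is a maximal block of consecutive bins where either channel is
    zero throughout; a run spanning midnight taints every day it touches.
    """
    tainted: set[pd.Timestamp] = set()
    limit_bins = max_hours * 60.0 / bin_width
    for col in ("motion_index", "steps"):
        z = (data[col].to_numpy() == 0).astype(np.int8)
        if not z.any():
            continue
        # run boundaries
        dz = np.diff(np.concatenate(([0], z, [0])))
        starts = np.flatnonzero(dz == 1)
        ends = np.flatnonzero(dz == -1)  # exclusive
        for s, e in zip(starts, ends):
            if (e - s) > limit_bins:
                span = data.index[s : e]
                tainted.update(span.normalize().unique())
    return tainted


def exclude_invalid_days(
    series: ActivitySeries,
    max_zero_run_hours: float = 12.0,
    trim_edges: bool = True,
) -> tuple[ActivitySeries, pd.DataFrame]:
    """Drop unreliable civil days and return the retained series plus a log.

    Removes (a) days touched by a zero-run of either channel strictly longer
    than ``max_zero_run_hours``; (b) the first and last calendar day (skipped
    when the series is already cleaned, which makes cleaning idempotent);
    (c) incomplete days.  The log has columns ``cow_id, day, rule``.
    """
    data = series.data
    log_rows: list[tuple[str, object, str]] = []
    if len(data) == 0:
        return replace(series, is_cleaned=True), pd.DataFrame(
            columns=["cow_id", "day", "rule"]
        )

    days = data.index.normalize()
    expected_bins = _DAY_MIN // series.bin_width
    counts = pd.Series(1, index=days).groupby(level=0).size()

    drop: dict[pd.Timestamp, str] = {}
    if trim_edges and not series.is_cleaned:
        drop[counts.index[0]] = "first_day"
        drop[counts.index[-1]] = "last_day"
    for day, n in counts.items():
        if n < expected_bins:
            drop.setdefault(day, "incomplete_day")
    for day in _zero_run_days(data, series.bin_width, max_zero_run_hours):
        drop.setdefault(day, f"zero_run_gt_{max_zero_run_hours:g}h")

    keep = ~days.isin(list(drop))
    for day, rule in sorted(drop.items()):
        log_rows.append((series.cow_id, day, rule))
    out = replace(series, data=data[keep], is_cleaned=True)
    if len(out.data) == 0:
        logger.warning("cow %s: no days survive cleaning", series.cow_id)
    log = pd.DataFrame(log_rows, columns=["cow_id", "day", "rule"])
    return out, log


def resample_15min(series: ActivitySeries) -> ActivitySeries:
    """Sum minute bins into 15-min bins anchored at :00/:15/:30/:45 UTC."""
    if series.bin_width == 15:
        return series
    if series.bin_width != 1:
        raise ValueError("resample_15min expects a minute-level series")
    res = series.data.groupby(series.data.index.floor("15min")).sum()
    # partial trailing/leading bins cannot occur on cleaned complete days,
    # but guard anyway: a bin is complete iff it received 15 minutes
    sizes = series.data.groupby(series.data.index.floor("15min")).size()
    partial = sizes.index[sizes < 15]
    if len(partial):
        logger.warning(
            "cow %s: dropping %d partial 15-min bin(s)", series.cow_id, len(partial)
        )
        res = res.drop(index=partial)
    res.index.name = "timestamp"
    return replace(series, data=res, bin_width=15)


def restrict_dim_window(
    series: ActivitySeries,
    meta: CowMeta,
    lo: int = 59,
    hi: int = 83,
    min_days: int = 15,
) -> tuple[ActivitySeries, bool]:
    """Keep days with days-in-milk in ``[lo, hi]``; flag short datasets.

    Returns the restricted series and ``excluded`` — True when fewer than
    ``min_days`` days remain (the dataset should then be dropped from the
    analysis).
    """
    if meta.calving_date is None:  # pragma: no cover - dataclass requires it
        raise ValueError(f"cow {series.cow_id}: calving date missing")
    calving = pd.Timestamp(meta.calving_date, tz=series.data.index.tz)
    dim = (series.data.index.normalize() - calving).days
    keep = (dim >= lo) & (dim <= hi)
    out = replace(series, data=series.data[keep])
    n_days = len(out.days())
    flagged = n_days < min_days
    if flagged:
        logger.info(
            "cow %s: only %d day(s) in %d-%d DIM (< %d) — flagged for exclusion",
            series.cow_id, n_days, lo, hi, min_days,
        )
    return out, flagged


def write_exclusion_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False)
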
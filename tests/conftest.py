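import numpy as np
import pandas as pd
import pytest

from herdrhythm import (
    HerdScenario,
    MilkingSchedule,
    ActivitySeries,
    simulate_herd,
)

UTC = "UTC"


def make_series(
    values,
    start="2021-01-10",
    bin_minutes=15,
    cow_id="cow1",
    tz=UTC,
    steps=None,
):
    """ActivitySeries from a 1-D motion-index array."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(
        pd.Timestamp(start, tz=tz), periods=len(values), freq=f"{bin_minutes}min"
    )
    data = pd.DataFrame(
        {
            "motion_index": values,
            "steps": np.asarray(steps, int) if steps is not None
            else np.maximum(values, 0).astype(int),
        },
        index=idx.rename("timestamp"),
    )
    return ActivitySeries(cow_id=cow_id, data=data, bin_width=bin_minutes)


def cosine_series(
    days=7, period_h=24.0, amplitude=10.0, baseline=20.0, bin_minutes=15,
    noise_sd=0.0, seed=0, start="2021-01-10", cow_id="cow1",
):
    n = days * 24 * 60 // bin_minutes
    h = np.arange(n) * bin_minutes / 60.0
    y = baseline + amplitude * np.cos(2 * np.pi * h / period_h)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_series(np.clip(y, 0, None), start=start,
                       bin_minutes=bin_minutes, cow_id=cow_id)


def constant_schedule(
    start="2021-01-01", days=14, tz=UTC,
    morning=("05:00", "06:30"), evening=("16:00", "17:30"),
):
    rows = []
    for i in range(days):
        d = pd.Timestamp(start, tz=tz) + pd.Timedelta(days=i)
        rows.append(
            dict(
                morning_start=d + pd.Timedelta(_hm(morning[0]), "m"),
                morning_end=d + pd.Timedelta(_hm(morning[1]), "m"),
                evening_start=d + pd.Timedelta(_hm(evening[0]), "m"),
                evening_end=d + pd.Timedelta(_hm(evening[1]), "m"),
            )
        )
    df = pd.DataFrame(rows)
    df.index = df["morning_start"].dt.normalize().rename("day")
    return MilkingSchedule(df)


def _hm(s):
    h, m = s.split(":")
    return int(h) * 60 + int(m)


@pytest.fixture(scope="session")
def small_herd():
    """A 6-cow, 16-day herd reused by read/pipeline tests."""
    scenario = HerdScenario(
        n_cows_per_group={"NOC": 2, "DTC": 2, "WDC": 2}, days=16, seed=11
    )
    return scenario, simulate_herd(scenario)
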
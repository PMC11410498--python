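"""Synthetic herd generator with known ground-truth rhythm structure.

Emulates the three input tables of a cow-calf-contact activity study —
minute-level per-cow activity (steps + motion index), a herd milking
schedule, and per-cow metadata — so that every downstream stage (cleaning,
spectral estimation, DFC, DI, mixed models) can be exercised and verified
without farm data.

Per-minute activity is a rectified sum of

* a day/night step (rates chosen to hit a target diurnal share),
* cosine components at configured periods (harmonics of 24 h by default),
* symmetric triangular activity bumps of ~30 min around each milking start,
* Gaussian noise;

estrus days attenuate the cosine components toward zero and inflate the
noise (a deliberately simple stand-in for estrus arrhythmia — no behavioral
realism is claimed), and sensor dropout inserts zero-runs of configurable
length.  Clipping negatives to zero slightly distorts component amplitudes;
downstream checks assert peak locations and power ratios, not absolute
power, so this is acceptable.

Randomness: one root seed; each cow gets a child stream derived by stable
hashing of its id, so adding a cow never changes another cow's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activity_io import ActivitySeries, CowMeta, MilkingSchedule

__all__ = ["HerdScenario", "simulate_herd", "inject_estrus", "write_tables"]

_NS_MIN = 60_000_000_000


@dataclass
class HerdScenario:
    """Configuration of one simulated herd.

    Defaults reproduce the motivating study's conditions: 36/25/18 cow
    datasets in NOC/DTC/WDC, a span covering 58-84 days in milk (so 59-83
    remain after edge trimming), milking starting around 05:00 and 16:00
    local (CET/CEST), and a dominant 24/7 h (~3.4 h) ultradian component.
    Amplitudes are in motion-index units per minute.
    """

    n_cows_per_group: dict[str, int] = field(
        default_factory=lambda: {"NOC": 36, "DTC": 25, "WDC": 18}
    )
    days: int = 27
    start_date: date = date(2021, 9, 1)
    tz: str = "Europe/Berlin"
    sampling_minutes: int = 1
    baseline: float = 20.0
    harmonic_amplitudes: dict[float, float] = field(
        default_factory=lambda: {24.0: 6.0, 12.0: 3.0, 4.8: 5.0, 24.0 / 7.0: 8.0}
    )
    diurnal_fraction: float = 0.55
    morning_milking: tuple[int, int] = (5, 0)  # local clock start (h, min)
    evening_milking: tuple[int, int] = (16, 0)
    milking_duration_min: int = 90
    milking_jitter_sd_min: float = 5.0
    milking_peak_height: float = 15.0
    milking_peak_width_min: float = 30.0
    estrus_probability: float = 0.6  # P(a cow shows one estrus day in the span)
    estrus_amplitude_multiplier: float = 0.1
    estrus_noise_inflation: float = 2.0
    dropout_prob_per_day: float = 0.01
    dropout_hours: tuple[float, float] = (2.0, 16.0)
    noise_sd: float = 4.0
    steps_per_mi: float = 0.35  # Poisson steps intensity per MI unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("days must be positive")
        if not self.n_cows_per_group or any(
            n <= 0 for n in self.n_cows_per_group.values()
        ):
            raise ValueError("each treatment group needs at least one cow")
        if any(a < 0 for a in self.harmonic_amplitudes.values()):
            raise ValueError("amplitudes must be nonnegative")
        if not 0.0 <= self.diurnal_fraction <= 1.0:
            raise ValueError("diurnal_fraction must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "HerdScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "start_date" in raw and isinstance(raw["start_date"], str):
            raw["start_date"] = date.fromisoformat(raw["start_date"])
        for key in ("morning_milking", "evening_milking", "dropout_hours"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "harmonic_amplitudes" in raw:
            raw["harmonic_amplitudes"] = {
                float(k): float(v) for k, v in raw["harmonic_amplitudes"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d


def _cow_rng(seed: int, cow_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, zlib.crc32(cow_id.encode())))
    )


def _local_ts(d: date, hm: tuple[int, int], tz: str, extra_min: float = 0.0) -> pd.Timestamp:
    base = datetime.combine(d, time(*hm)) + timedelta(minutes=float(extra_min))
    return pd.Timestamp(base).tz_localize(tz)


def _make_schedule(scenario: HerdScenario) -> MilkingSchedule:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(0, 0))
    )
    rows = []
    for i in range(scenario.days):
        d = scenario.start_date + timedelta(days=i)
        jm = round(rng.normal(0.0, scenario.milking_jitter_sd_min))
        je = round(rng.normal(0.0, scenario.milking_jitter_sd_min))
        ms = _local_ts(d, scenario.morning_milking, scenario.tz, jm)
        es = _local_ts(d, scenario.evening_milking, scenario.tz, je)
        rows.append(
            dict(
                morning_start=ms,
                morning_end=ms + pd.Timedelta(minutes=scenario.milking_duration_min),
                evening_start=es,
                evening_end=es + pd.Timedelta(minutes=scenario.milking_duration_min),
            )
        )
    df = pd.DataFrame(rows)
    df.index = df["morning_start"].dt.normalize().rename("day")
    return MilkingSchedule(df)


def _day_night_rates(scenario: HerdScenario) -> tuple[float, float]:
    f = scenario.diurnal_fraction
    return 2.0 * scenario.baseline * f, 2.0 * scenario.baseline * (1.0 - f)


def _nominal_minutes(hm: tuple[int, int]) -> int:
    return hm[0] * 60 + hm[1]


def simulate_herd(
    scenario: HerdScenario,
) -> tuple[list[ActivitySeries], MilkingSchedule, list[CowMeta], pd.DataFrame]:
    """Generate the full herd: activity series, milking schedule, metadata,
    and a ground-truth table (one row per cow and UTC civil day:
    ``dominant_period_h``, ``true_diurnality``, ``estrus``,
    ``dropout_minutes``).

    Reproducible bit-for-bit for a fixed scenario (including the seed).
    """
    tz = scenario.tz
    schedule = _make_schedule(scenario)

    start = pd.Timestamp(scenario.start_date).tz_localize(tz)
    end = (pd.Timestamp(scenario.start_date) + pd.Timedelta(days=scenario.days)).tz_localize(tz)
    idx = pd.date_range(start, end, freq=f"{scenario.sampling_minutes}min",
                        inclusive="left")
    n = len(idx)
    hours = np.arange(n) * scenario.sampling_minutes / 60.0

    # local clock minute-of-day for the day/night step
    mod = idx.hour * 60 + idx.minute  # idx is tz-aware local
    m_start = _nominal_minutes(scenario.morning_milking)
    m_end = m_start + scenario.milking_duration_min
    e_start = _nominal_minutes(scenario.evening_milking)
    e_end = e_start + scenario.milking_duration_min
    r_day, r_night = _day_night_rates(scenario)
    step = np.full(n, 0.5 * (r_day + r_night))
    step[(mod >= m_end) & (mod < e_start)] = r_day
    step[(mod >= e_end) | (mod < m_start)] = r_night

    # milking-anchored triangular bumps (same for all cows; herd routine)
    bumps = np.zeros(n)
    half_w = scenario.milking_peak_width_min / 2.0
    for col in ("morning_start", "evening_start"):
        for ts in schedule.data[col]:
            center = (ts.tz_convert(idx.tz).value - idx[0].value) / _NS_MIN
            lo = max(0, int(np.floor(center - half_w)))
            hi = min(n - 1, int(np.ceil(center + half_w)))
            if hi < 0 or lo > n - 1:
                continue
            offs = np.arange(lo, hi + 1) * scenario.sampling_minutes - center
            bumps[lo : hi + 1] += scenario.milking_peak_height * np.clip(
                1.0 - np.abs(offs) / half_w, 0.0, None
            )

    # UTC civil-day codes per sample (analysis days are UTC days)
    utc_days = idx.tz_convert("UTC").normalize()
    day_codes, unique_days = pd.factorize(utc_days, sort=True)
    unique_days = pd.DatetimeIndex(unique_days)
    n_days = len(unique_days)

    periods = np.array(sorted(scenario.harmonic_amplitudes), dtype=float)
    amps = np.array([scenario.harmonic_amplitudes[p] for p in sorted(scenario.harmonic_amplitudes)])
    dominant = float(periods[np.argmax(amps)]) if len(periods) else np.nan
    true_di = 2.0 * scenario.diurnal_fraction - 1.0

    meta_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(0, 1))
    )
    series_list: list[ActivitySeries] = []
    metas: list[CowMeta] = []
    gt_rows: list[dict] = []

    for grp, n_cows in scenario.n_cows_per_group.items():
        for k in range(n_cows):
            cow_id = f"{grp}{k + 1:03d}"
            rng = _cow_rng(scenario.seed, cow_id)

            # cosine components with cow-specific phases
            harm = np.zeros(n)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=len(periods))
            for p, a, ph in zip(periods, amps, phases):
                if a > 0:
                    harm += a * np.cos(2.0 * np.pi * hours / p + ph)

            # estrus days (UTC civil days, excluding trimmed edge days)
            estrus_days: list[pd.Timestamp] = []
            if n_days > 2 and rng.random() < scenario.estrus_probability:
                estrus_days = [unique_days[int(rng.integers(1, n_days - 1))]]
            est_mult = np.ones(n)
            noise_mult = np.ones(n)
            for ed in estrus_days:
                m = day_codes == unique_days.get_loc(ed)
                est_mult[m] = scenario.estrus_amplitude_multiplier
                noise_mult[m] = scenario.estrus_noise_inflation

            noise = rng.normal(0.0, scenario.noise_sd, n) if scenario.noise_sd > 0 else 0.0
            signal = np.clip(step + bumps + harm * est_mult + noise * noise_mult, 0.0, None)
            mi = np.round(signal, 3)
            steps = rng.poisson(scenario.steps_per_mi * signal) if scenario.steps_per_mi > 0 else np.zeros(n, int)

            # sensor dropout: zero-runs
            dropout_min = np.zeros(n_days)
            if scenario.dropout_prob_per_day > 0:
                for di in range(n_days):
                    if rng.random() < scenario.dropout_prob_per_day:
                        dur_h = rng.uniform(*scenario.dropout_hours)
                        day_pos = np.flatnonzero(day_codes == di)
                        s = int(rng.integers(0, len(day_pos)))
                        run = int(round(dur_h * 60.0 / scenario.sampling_minutes))
                        lo = day_pos[s]
                        hi = min(n, lo + run)
                        mi[lo:hi] = 0.0
                        steps[lo:hi] = 0
                        # attribute dropped minutes to the days the run touches
                        for dj in np.unique(day_codes[lo:hi]):
                            dropout_min[dj] += int(
                                ((day_codes[lo:hi] == dj).sum()) * scenario.sampling_minutes
                            )

            data = pd.DataFrame(
                {"motion_index": mi, "steps": steps.astype(int)},
                index=pd.DatetimeIndex(idx, name="timestamp"),
            )
            series_list.append(
                ActivitySeries(cow_id=cow_id, data=data,
                               bin_width=scenario.sampling_minutes)
            )
            metas.append(
                CowMeta(
                    cow_id=cow_id,
                    herd="polled" if meta_rng.random() < 0.5 else "horned",
                    treatment=grp,
                    parity="multiparous" if meta_rng.random() < 0.6 else "primiparous",
                    lactation_number=int(meta_rng.integers(1, 5)),
                    calving_date=scenario.start_date - timedelta(days=58),
                    estrus_dates=tuple(ed.date() for ed in estrus_days),
                )
            )
            estrus_set = {ed for ed in estrus_days}
            for di, day in enumerate(unique_days):
                gt_rows.append(
                    dict(
                        cow_id=cow_id,
                        day=day.date(),
                        dominant_period_h=dominant,
                        true_diurnality=true_di,
                        estrus=day in estrus_set,
                        dropout_minutes=float(dropout_min[di]),
                    )
                )

    ground_truth = pd.DataFrame(gt_rows)
    return series_list, schedule, metas, ground_truth


def inject_estrus(
    series: ActivitySeries,
    days,
    multiplier: float,
    extra_noise_sd: float = 0.0,
    seed: int = 0,
) -> ActivitySeries:
    """Attenuate rhythm and optionally inflate noise on the listed civil days.

    On each listed day the motion index is shrunk toward that day's mean by
    ``multiplier`` (0 flattens the day completely, 1 leaves it untouched) and
    independent Gaussian noise of SD ``extra_noise_sd`` is added; the result
    is re-rectified.  Other days are bit-identical.  With ``multiplier == 1``
    and no extra noise the whole series is returned unchanged.

    Raises if a listed day is absent from the series.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    norm_days = series.data.index.normalize()
    present = set(norm_days.unique())
    targets = []
    for d in days:
        ts = pd.Timestamp(d)
        if ts.tz is None:
            ts = ts.tz_localize(norm_days.tz)
        ts = ts.normalize()
        if ts not in present:
            raise ValueError(f"cow {series.cow_id}: day {ts.date()} not in series")
        targets.append(ts)

    if multiplier == 1.0 and extra_noise_sd == 0.0:
        return replace(series, data=series.data.copy())

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2, zlib.crc32(series.cow_id.encode())))
    )
    data = series.data.copy()
    for ts in targets:
        m = norm_days == ts
        v = data.loc[m, "motion_index"].to_numpy()
        mean = v.mean()
        v2 = mean + multiplier * (v - mean)
        if extra_noise_sd > 0:
            v2 = v2 + rng.normal(0.0, extra_noise_sd, len(v2))
        data.loc[m, "motion_index"] = np.round(np.clip(v2, 0.0, None), 3)
    return replace(series, data=data)


def write_tables(
    out_dir: str | Path,
    series_list: list[ActivitySeries],
    schedule: MilkingSchedule,
    metas: list[CowMeta],
    ground_truth: pd.DataFrame,
) -> dict[str, Path]:
    """Write activity/milking/cows/ground-truth CSVs (ISO timestamps with offset)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in ("activity", "milking", "cows", "ground_truth")}

    frames = []
    for s in series_list:
        df = s.data.reset_index()
        df.insert(0, "cow_id", s.cow_id)
        frames.append(df)
    act = pd.concat(frames, ignore_index=True)
    act["timestamp"] = act["timestamp"].map(lambda t: t.isoformat())
    act.to_csv(paths["activity"], index=False)

    sched = schedule.data.copy()
    for col in MilkingSchedule.COLUMNS:
        sched[col] = sched[col].map(lambda t: t.isoformat())
    sched.to_csv(paths["milking"], index=False)

    pd.DataFrame(
        [
            dict(
                cow_id=m.cow_id,
                herd=m.herd,
                treatment=m.treatment,
                parity=m.parity,
                lactation_number=m.lactation_number,
                calving_date=m.calving_date.isoformat(),
                estrus_dates=";".join(d.isoformat() for d in m.estrus_dates),
                health_excluded=m.health_excluded,
            )
            for m in metas
        ]
    ).to_csv(paths["cows"], index=False)

    ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths
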
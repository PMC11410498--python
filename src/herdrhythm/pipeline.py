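"""End-to-end orchestration: simulate (or load) -> clean -> spectra/DFC ->
DI -> harmonic summary -> mixed models, with every stage's output written as
tidy CSV and a run manifest for provenance.

Rerunning with the same configuration and seed reproduces every numeric
output bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .activity_io import (
    ActivitySeries,
    CowMeta,
    MilkingSchedule,
    convert_to_gmt,
    exclude_invalid_days,
    read_activity,
    read_metadata,
    read_schedule,
    resample_15min,
    restrict_dim_window,
)
from .diurnality import diurnality_index, milking_deviation, sliding_day_night
from .mixed_models import fit_dfc_model, fit_di_model
from .rhythm_metrics import harmonic_summary, median_split, sliding_dfc
from .synthetic_data import HerdScenario, simulate_herd, write_tables

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized into the output dir)."""

    scenario: dict = field(default_factory=dict)  # HerdScenario overrides
    activity_path: str | None = None  # read tables instead of simulating
    milking_path: str | None = None
    cows_path: str | None = None
    tz: str = "Europe/Berlin"
    dim_lo: int = 59
    dim_hi: int = 83
    min_dim_days: int = 15
    alpha: float = 0.05
    window_days: int = 7
    min_window_days: int = 5
    harmonic_n_max: int = 48
    fit_models: bool = True
    write_input_tables: bool = False
    out_dir: str = "herdrhythm_run"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_or_simulate(config: RunConfig):
    if config.activity_path:
        if not (config.milking_path and config.cows_path):
            raise ValueError("activity_path requires milking_path and cows_path")
        series = read_activity(config.activity_path, tz=config.tz)
        schedule = read_schedule(config.milking_path, tz=config.tz)
        metas = read_metadata(config.cows_path)
        return series, schedule, metas, None
    scen_kwargs = dict(config.scenario)
    scen_kwargs.setdefault("seed", config.seed)
    scenario = HerdScenario(**scen_kwargs)
    return (*simulate_herd(scenario), )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns a dict with the in-memory results (frames and model results).
    Any stage failure raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate/load"
        series_list, schedule, metas, ground_truth = _load_or_simulate(config)
        meta_by_id = {m.cow_id: m for m in metas}
        if config.write_input_tables and ground_truth is not None:
            write_tables(out / "input_tables", series_list, schedule, metas, ground_truth)

        stage = "clean"
        logs = []
        cleaned: list[ActivitySeries] = []
        excluded_cows: list[str] = []
        schedule_utc = None
        for s in series_list:
            s_utc, schedule_utc = convert_to_gmt(s, schedule)
            s_cl, log = exclude_invalid_days(s_utc)
            logs.append(log)
            s15 = resample_15min(s_cl)
            s_dim, flagged = restrict_dim_window(
                s15, meta_by_id[s.cow_id], config.dim_lo, config.dim_hi,
                config.min_dim_days,
            )
            if flagged or meta_by_id[s.cow_id].health_excluded:
                excluded_cows.append(s.cow_id)
                continue
            cleaned.append(s_dim)
        exclusion_log = (
            pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
        )
        exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
        pd.Series(excluded_cows, name="cow_id").to_csv(
            out / "excluded_cows.csv", index=False
        )

        stage = "dfc"
        rec_frames, sig_frames = [], []
        for s in cleaned:
            rec, sig = sliding_dfc(
                s,
                alpha=config.alpha,
                window_days=config.window_days,
                min_days=config.min_window_days,
            )
            if len(rec):
                rec_frames.append(rec)
            if len(sig):
                sig_frames.append(sig)
        dfc_records = pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame()
        significant = pd.concat(sig_frames, ignore_index=True) if sig_frames else pd.DataFrame()
        dfc_records, dfc_median = median_split(dfc_records)
        dfc_records.to_csv(out / "dfc_records.csv", index=False)
        significant.to_csv(out / "significant_frequencies.csv", index=False)

        stage = "di"
        windows = sliding_day_night(schedule_utc, window_days=config.window_days)
        di_frames = [diurnality_index(s, windows) for s in cleaned]
        di_records = (
            pd.concat([f for f in di_frames if len(f)], ignore_index=True)
            if any(len(f) for f in di_frames)
            else pd.DataFrame()
        )
        di_records.to_csv(out / "di_records.csv", index=False)
        deviations = milking_deviation(schedule_utc)
        deviations.to_csv(out / "milking_deviation.csv")

        stage = "harmonics"
        groups = {m.cow_id: m.treatment for m in metas}
        catalog = None
        if len(significant):
            catalog = harmonic_summary(significant, {c: groups[c] for c in
                                                     significant["cow_id"].unique()} |
                                       {s.cow_id: groups[s.cow_id] for s in cleaned})
            catalog.counts.to_csv(out / "harmonic_counts.csv", index=False)
            catalog.proportions.to_csv(out / "harmonic_proportions.csv", index=False)
            catalog.per_cow.to_csv(out / "harmonic_periods_per_cow.csv")

        stage = "model frames"
        dfc_frame = di_frame = None
        if len(dfc_records):
            dfc_frame = _dfc_model_frame(dfc_records, deviations, metas)
            dfc_frame.to_csv(out / "dfc_model_frame.csv", index=False)
        if len(di_records):
            di_frame = _di_model_frame(di_records, metas)
            di_frame.to_csv(out / "di_model_frame.csv", index=False)

        stage = "models"
        dfc_result = di_result = None
        if config.fit_models and dfc_frame is not None and dfc_frame["dfc_binary"].nunique() > 1:
            dfc_result = fit_dfc_model(dfc_frame)
            dfc_result.table.to_csv(out / "dfc_model.csv", index=False)
        if config.fit_models and di_frame is not None and len(di_frame):
            di_result = fit_di_model(di_frame)
            di_result.table.to_csv(out / "di_model.csv", index=False)
            di_result.emmeans.to_csv(out / "di_emmeans.csv", index=False)

        stage = "manifest"
        manifest = dict(
            package_version=__version__,
            config=asdict(config),
            seed=config.seed,
            n_cows_input=len(series_list),
            n_cows_analyzed=len(cleaned),
            dfc_median=dfc_median,
            n_dfc_records=int(len(dfc_records)),
            n_di_records=int(len(di_records)),
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return dict(
        cleaned=cleaned,
        schedule=schedule_utc,
        metas=metas,
        ground_truth=ground_truth,
        dfc_records=dfc_records,
        significant=significant,
        di_records=di_records,
        deviations=deviations,
        catalog=catalog,
        dfc_frame=dfc_frame,
        di_frame=di_frame,
        dfc_result=dfc_result,
        di_result=di_result,
        manifest=manifest,
    )


def _estrus_lookup(metas: list[CowMeta]):
    return {m.cow_id: {pd.Timestamp(d) for d in m.estrus_dates} for m in metas}


def _dfc_model_frame(
    dfc_records: pd.DataFrame, deviations: pd.DataFrame, metas: list[CowMeta]
) -> pd.DataFrame:
    """Cow-day frame for the binomial DFC model (day = window end day)."""
    meta = {m.cow_id: m for m in metas}
    estrus = _estrus_lookup(metas)
    df = dfc_records.copy()
    day_naive = df["window_end_day"].dt.tz_localize(None).dt.normalize()
    df["estrus"] = [
        int(d in estrus[c]) for c, d in zip(df["cow_id"], day_naive)
    ]
    dev = deviations.copy()
    dev.index = dev.index.tz_localize(None)
    df["milk_dev_evening"] = day_naive.map(dev["deviation_evening"]).to_numpy()
    df["treatment"] = df["cow_id"].map(lambda c: meta[c].treatment)
    df["cluster"] = df["cow_id"] + "/L" + df["cow_id"].map(
        lambda c: str(meta[c].lactation_number)
    )
    return df.dropna(subset=["milk_dev_evening"]).reset_index(drop=True)


def _di_model_frame(di_records: pd.DataFrame, metas: list[CowMeta]) -> pd.DataFrame:
    meta = {m.cow_id: m for m in metas}
    estrus = _estrus_lookup(metas)
    df = di_records.copy()
    day_naive = df["day"].dt.tz_localize(None).dt.normalize()
    df["estrus"] = [int(d in estrus[c]) for c, d in zip(df["cow_id"], day_naive)]
    df["treatment"] = df["cow_id"].map(lambda c: meta[c].treatment)
    df["parity"] = df["cow_id"].map(lambda c: meta[c].parity)
    df["cluster"] = df["cow_id"] + "/L" + df["cow_id"].map(
        lambda c: str(meta[c].lactation_number)
    )
    return df.reset_index(drop=True)
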
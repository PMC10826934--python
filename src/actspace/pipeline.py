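"""End-to-end orchestration: io -> clean -> quality -> home time -> concordance.

A single :class:`RunConfig` (built in code or loaded from YAML/JSON) names
the input files and analysis parameters; :func:`run_pipeline` executes the
stages in order and writes every table as CSV plus the cleaning report as
JSON and a run log echoing versions, seed and parameters. Any stage
failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cleaning import clean_cohort
from .ema import agreement_summary, concordance_by_stratum, match_cohort
from .home_time import WakeWindow, build_home_geometry, group_wake_time_ci, wake_time_cohort
from .io_types import (
    StudyWindow,
    load_ema_csv,
    load_gps_csv,
    load_homes,
    load_meta_csv,
    load_setting_layer,
)
from .quality import (
    OutlierThresholds,
    group_summary,
    outlier_incidence,
    participant_quality_summary,
)

logger = logging.getLogger("actspace")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


@dataclass
class RunConfig:
    gps_csv: str
    ema_csv: str
    meta_csv: str
    homes_geojson: str
    setting_layer_geojson: str
    out_dir: str
    window_start: str  # local ISO date or datetime
    window_days: int = 7
    timezone: str = "America/New_York"
    k_sd: float = 3.0
    v_max: float = 250.0
    abs_distance_threshold: float | None = None
    time_gap_max: float = 3600.0
    distance_gap_max: float = 1000.0
    accuracy_max: float = 1000.0
    buffers: Sequence[int] = (20, 50, 100)
    wake_start: str = "08:00"
    wake_end: str = "20:30"
    ema_tolerance_s: float = 60.0
    by_device_tables: bool = False
    log_level: str = "INFO"
    seed: int | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def study_window(self) -> StudyWindow:
        return StudyWindow.from_local_date(self.window_start, self.window_days, self.timezone)

    def wake_window(self) -> WakeWindow:
        return WakeWindow(time.fromisoformat(self.wake_start), time.fromisoformat(self.wake_end))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages and write the report bundle; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    window = config.study_window()
    wake = config.wake_window()
    written: dict[str, Path] = {}

    @_stage("io")
    def _load():
        trajectories, load_report = load_gps_csv(
            config.gps_csv, timezone=config.timezone, window=window
        )
        metas = load_meta_csv(config.meta_csv)
        emas = load_ema_csv(config.ema_csv, timezone=config.timezone)
        homes_raw = load_homes(config.homes_geojson)
        layer = load_setting_layer(config.setting_layer_geojson)
        homes = {
            pid: build_home_geometry(pid, h.footprint, tuple(int(b) for b in config.buffers if b))
            for pid, h in homes_raw.items()
        }
        return trajectories, load_report, metas, emas, homes, layer

    trajectories, load_report, metas, emas, homes, layer = _load()

    @_stage("clean")
    def _clean():
        return clean_cohort(
            trajectories,
            window,
            k=config.k_sd,
            v_max=config.v_max,
            abs_distance_threshold=config.abs_distance_threshold,
        )

    cleaned, report = _clean()
    written["cleaning_report"] = out / "cleaning_report.json"
    written["cleaning_report"].write_text(report.to_json())
    logger.info("cleaning report: %s", report.to_json())

    @_stage("quality")
    def _quality():
        qualities = {
            pid: participant_quality_summary(traj, window) for pid, traj in cleaned.items()
        }
        thresholds = OutlierThresholds(
            config.time_gap_max, config.distance_gap_max, config.accuracy_max
        )
        tables = {
            "quality_by_residence": group_summary(qualities, metas, "residence"),
            "quality_by_device": group_summary(qualities, metas, "device"),
            "outlier_incidence": outlier_incidence(cleaned, metas, layer, thresholds),
        }
        if config.by_device_tables:
            tables["outlier_incidence_by_device"] = outlier_incidence(
                cleaned, metas, layer, thresholds, stratify_by_device=True
            )
        return tables

    for name, frame in _quality().items():
        written[name] = out / f"{name}.csv"
        frame.to_csv(written[name], index=False)

    @_stage("home_time")
    def _home():
        props = wake_time_cohort(cleaned, homes, list(config.buffers), wake, window)
        return props, group_wake_time_ci(props, metas)

    props, ci_table = _home()
    written["wake_time_at_home"] = out / "wake_time_at_home.csv"
    props.to_csv(written["wake_time_at_home"], index=False)
    written["wake_time_group_ci"] = out / "wake_time_group_ci.csv"
    ci_table.to_csv(written["wake_time_group_ci"], index=False)

    @_stage("ema")
    def _ema():
        pairs, unmatched = match_cohort(emas, cleaned, config.ema_tolerance_s)
        buffers = [int(b) for b in config.buffers if int(b) > 0]
        tables = concordance_by_stratum(pairs, homes, metas, buffers, unmatched)
        rows = pd.DataFrame([t.as_row() for t in tables])
        return rows, agreement_summary(tables)

    conc_rows, agree = _ema()
    written["concordance"] = out / "concordance.csv"
    conc_rows.to_csv(written["concordance"], index=False)
    written["agreement_summary"] = out / "agreement_summary.csv"
    agree.to_csv(written["agreement_summary"], index=False)

    run_log = {
        "actspace_version": __version__,
        "python": sys.version,
        "platform": platform.platform(),
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "n_input_rows": load_report.n_rows,
        "n_rejected_rows": load_report.n_rejected,
    }
    written["run_log"] = out / "run_log.json"
    written["run_log"].write_text(json.dumps(run_log, indent=2, default=str))
    return written
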
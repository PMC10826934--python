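"""Participant- and point-level GPS quality metrics.

Two distinct pooling universes are deliberately kept apart:

* :func:`participant_quality_summary` + :func:`group_summary` compute each
  metric per participant first, then summarize those participant-level
  values per group (statistics OF statistics) — the convention for cohort
  quality tables.
* :func:`outlier_incidence` pools at the GPS-point level within each
  residence × activity-setting cell, which is where rare outliers
  (time gap > 1 h, distance gap > 1 km, accuracy > 1 km) are counted.

A gap inherits the setting label and timestamp of its LATER point.
Undefined statistics (fewer than two gaps) propagate as NaN, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cleaning import consecutive_gaps
from .io_types import (
    ParticipantMeta,
    Setting,
    SettingLayer,
    StudyWindow,
    Trajectory,
    assign_points_setting,
)

__all__ = [
    "OutlierThresholds",
    "ParticipantQuality",
    "participation_days",
    "temporal_coverage",
    "participant_quality_summary",
    "group_summary",
    "outlier_incidence",
]


@dataclass(frozen=True)
class OutlierThresholds:
    """Cut-offs defining a point-level outlier."""

    time_gap_max: float = 3600.0  # seconds (1 hour)
    distance_gap_max: float = 1000.0  # meters (1 km)
    accuracy_max: float = 1000.0  # meters (1 km)

    def __post_init__(self) -> None:
        if min(self.time_gap_max, self.distance_gap_max, self.accuracy_max) <= 0:
            raise ValueError("all outlier thresholds must be > 0")


@dataclass
class Stats:
    mean: float
    sd: float
    median: float

    @classmethod
    def of(cls, values: np.ndarray) -> "Stats":
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            return cls(float("nan"), float("nan"), float("nan"))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
        return cls(float(np.mean(values)), sd, float(np.median(values)))


@dataclass
class ParticipantQuality:
    participant_id: str
    time_gap_stats: Stats
    distance_gap_stats: Stats
    accuracy_stats: Stats
    n_days_participated: int
    temporal_coverage: float
    n_points: int
    defined: bool = field(default=True)  # False when < 2 gaps

    def as_row(self) -> dict[str, float]:
        return {
            "participant_id": self.participant_id,
            "time_gap_mean": self.time_gap_stats.mean,
            "time_gap_sd": self.time_gap_stats.sd,
            "time_gap_median": self.time_gap_stats.median,
            "distance_gap_mean": self.distance_gap_stats.mean,
            "distance_gap_sd": self.distance_gap_stats.sd,
            "distance_gap_median": self.distance_gap_stats.median,
            "accuracy_mean": self.accuracy_stats.mean,
            "accuracy_sd": self.accuracy_stats.sd,
            "accuracy_median": self.accuracy_stats.median,
            "n_days_participated": self.n_days_participated,
            "temporal_coverage": self.temporal_coverage,
            "n_points": self.n_points,
        }


def participation_days(
    trajectory: Trajectory, window: StudyWindow, timezone: str | None = None
) -> int:
    """Distinct local calendar dates in the window with at least one point."""
    if len(trajectory) == 0:
        return 0
    tz = timezone or window.timezone
    ts = trajectory.points["timestamp"]
    ts = ts[(ts >= window.start) & (ts < window.end)]
    if ts.empty:
        return 0
    return int(ts.dt.tz_convert(tz).dt.normalize().nunique())


def temporal_coverage(trajectory: Trajectory, window: StudyWindow) -> float:
    """Fraction of whole window minutes containing at least one fix.

    A participant reporting a point every minute of a 7-day window scores
    1.0; full coverage of exactly one of seven days scores 1440/10080.
    """
    total = window.total_minutes
    if total == 0 or len(trajectory) == 0:
        return 0.0
    ts = trajectory.points["timestamp"]
    ts = ts[(ts >= window.start) & (ts < window.end)]
    if ts.empty:
        return 0.0
    # minute index relative to window start; robust to windows starting off-minute
    offset = (ts - window.start).dt.total_seconds() // 60
    return float(offset.nunique() / total)


def participant_quality_summary(
    trajectory: Trajectory, window: StudyWindow
) -> ParticipantQuality:
    """Per-participant quality metrics on a cleaned trajectory."""
    gaps = consecutive_gaps(trajectory)
    defined = len(gaps) >= 2
    acc = trajectory.points["accuracy"].to_numpy(dtype=float) if len(trajectory) else np.array([])
    return ParticipantQuality(
        participant_id=trajectory.participant_id,
        time_gap_stats=Stats.of(gaps["time_gap"].to_numpy()) if defined else Stats.of([]),
        distance_gap_stats=Stats.of(gaps["distance_gap"].to_numpy()) if defined else Stats.of([]),
        accuracy_stats=Stats.of(acc),
        n_days_participated=participation_days(trajectory, window),
        temporal_coverage=temporal_coverage(trajectory, window),
        n_points=len(trajectory),
        defined=defined,
    )


_METRICS = [
    "time_gap_mean", "time_gap_sd", "time_gap_median",
    "distance_gap_mean", "distance_gap_sd", "distance_gap_median",
    "accuracy_mean", "accuracy_sd", "accuracy_median",
    "n_days_participated", "temporal_coverage", "n_points",
]


def group_summary(
    qualities: Mapping[str, ParticipantQuality],
    metas: Mapping[str, ParticipantMeta],
    group_by: str = "residence",
) -> pd.DataFrame:
    """Cohort quality table: per-group mean/SD/median of participant metrics.

    ``group_by`` is ``residence`` (urban vs non-urban) or ``device``
    (android vs ios). Also reports %% iOS users and N participants per
    group. Long format: one row per (group, metric, statistic).
    """
    if group_by not in ("residence", "device"):
        raise ValueError("group_by must be 'residence' or 'device'")
    rows = []
    for pid, q in qualities.items():
        meta = metas[pid]
        key = (
            meta.residence_setting.value
            if group_by == "residence"
            else meta.device_os.value
        )
        row = q.as_row()
        row["group"] = key
        row["is_ios"] = meta.device_os.value == "ios"
        rows.append(row)
    if not rows:
        warnings.warn("no participants to summarize", stacklevel=2)
        return pd.DataFrame(columns=["group", "metric", "mean", "sd", "median"])
    frame = pd.DataFrame(rows)

    out = []
    for key, grp in frame.groupby("group", sort=True):
        for metric in _METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            s = Stats.of(vals)
            out.append(
                {
                    "group": key,
                    "metric": metric,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                }
            )
        out.append(
            {
                "group": key,
                "metric": "pct_ios_users",
                "mean": 100.0 * grp["is_ios"].mean(),
                "sd": np.nan,
                "median": np.nan,
            }
        )
        out.append(
            {"group": key, "metric": "n_participants", "mean": float(len(grp)), "sd": np.nan, "median": np.nan}
        )
    return pd.DataFrame(out)


def outlier_incidence(
    trajectories: Mapping[str, Trajectory],
    metas: Mapping[str, ParticipantMeta],
    setting_layer: SettingLayer,
    thresholds: OutlierThresholds = OutlierThresholds(),
    stratify_by_device: bool = False,
) -> pd.DataFrame:
    """Point-level quality and outlier shares by residence × point setting.

    Each GPS point is labeled by the setting polygon containing it; a gap
    carries its later point's label. Per cell the table reports mean / SD /
    median of time gap, distance gap and accuracy, the share of gaps above
    the time and distance cut-offs, the share of points above the accuracy
    cut-off, N points, and the %% of the residence stratum's points falling
    in the cell. With ``stratify_by_device`` the cells are additionally
    split by operating system.
    """
    point_frames = []
    gap_frames = []
    for pid, traj in trajectories.items():
        meta = metas[pid]
        pts = traj.points
        if len(pts) == 0:
            continue
        labels = assign_points_setting(
            pts["lon"].to_numpy(dtype=float), pts["lat"].to_numpy(dtype=float), setting_layer
        )
        pf = pd.DataFrame(
            {
                "residence": meta.residence_setting.value,
                "device": meta.device_os.value,
                "setting": labels,
                "accuracy": pts["accuracy"].to_numpy(dtype=float),
            }
        )
        point_frames.append(pf)
        gaps = consecutive_gaps(traj)
        if len(gaps):
            gf = pd.DataFrame(
                {
                    "residence": meta.residence_setting.value,
                    "device": meta.device_os.value,
                    # later-point attribution: gap i ends at point i+1
                    "setting": labels[1:],
                    "time_gap": gaps["time_gap"].to_numpy(),
                    "distance_gap": gaps["distance_gap"].to_numpy(),
                }
            )
            gap_frames.append(gf)
    if not point_frames:
        return pd.DataFrame()
    points = pd.concat(point_frames, ignore_index=True)
    gaps = pd.concat(gap_frames, ignore_index=True) if gap_frames else pd.DataFrame(
        columns=["residence", "device", "setting", "time_gap", "distance_gap"]
    )

    strata = ["residence", "setting"] + (["device"] if stratify_by_device else [])
    total_keys = ["residence"] + (["device"] if stratify_by_device else [])
    stratum_totals = points.groupby(total_keys).size()

    cells = []
    all_settings = [Setting.urban.value, Setting.non_urban.value]
    if (points["setting"] == Setting.unknown.value).any():
        all_settings.append(Setting.unknown.value)
    residences = sorted(points["residence"].unique())
    devices = sorted(points["device"].unique()) if stratify_by_device else [None]
    for residence in residences:
        for setting in all_settings:
            for device in devices:
                pmask = (points["residence"] == residence) & (points["setting"] == setting)
                gmask = (gaps["residence"] == residence) & (gaps["setting"] == setting)
                total_key = residence
                if device is not None:
                    pmask &= points["device"] == device
                    gmask &= gaps["device"] == device
                    total_key = (residence, device)
                psub = points.loc[pmask]
                gsub = gaps.loc[gmask]
                tg = Stats.of(gsub["time_gap"].to_numpy())
                dg = Stats.of(gsub["distance_gap"].to_numpy())
                ac = Stats.of(psub["accuracy"].to_numpy())
                n_pts = len(psub)
                cell = {
                    "residence": residence,
                    "setting": setting,
                    "time_gap_mean": tg.mean, "time_gap_sd": tg.sd, "time_gap_median": tg.median,
                    "pct_time_gap_outlier": (
                        100.0 * float((gsub["time_gap"] > thresholds.time_gap_max).mean())
                        if len(gsub) else np.nan
                    ),
                    "distance_gap_mean": dg.mean, "distance_gap_sd": dg.sd, "distance_gap_median": dg.median,
                    "pct_distance_gap_outlier": (
                        100.0 * float((gsub["distance_gap"] > thresholds.distance_gap_max).mean())
                        if len(gsub) else np.nan
                    ),
                    "accuracy_mean": ac.mean, "accuracy_sd": ac.sd, "accuracy_median": ac.median,
                    "pct_accuracy_outlier": (
                        100.0 * float((psub["accuracy"] > thresholds.accuracy_max).mean())
                        if n_pts else np.nan
                    ),
                    "n_points": n_pts,
                    "pct_points_by_location": (
                        100.0 * n_pts / stratum_totals[total_key]
                        if stratum_totals.get(total_key, 0) else np.nan
                    ),
                }
                if device is not None:
                    cell["device"] = device
                cells.append(cell)
    frame = pd.DataFrame(cells)
    front = strata
    return frame[front + [c for c in frame.columns if c not in front]]
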
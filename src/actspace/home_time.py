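"""Home geofencing and wake-time-at-home estimation.

Being "at home" is operationalized as a GPS fix falling inside the home
building footprint or one of its outward extensions (20 / 50 / 100 m
buffers). Buffering happens in meters: the footprint is projected into a
local azimuthal-equidistant frame centered on its centroid, buffered there,
and reprojected to WGS84. At building scale the projection distortion is
far below GPS accuracy.

The wake-time-at-home proportion labels every minute of the daily wake
window (08:00-20:30 local by default) home / away / no-data using the fix
nearest the minute midpoint, and reports home / (home + away); minutes
without any fix are excluded from the denominator rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import time
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .cleaning import EARTH_RADIUS_M
from .io_types import HomeGeometry, ParticipantMeta, StudyWindow, Trajectory

__all__ = [
    "WakeWindow",
    "aeqd_forward",
    "aeqd_inverse",
    "buffer_home",
    "build_home_geometry",
    "classify_at_home",
    "at_home_minute_series",
    "wake_time_at_home",
    "wake_time_cohort",
    "group_proportion_ci",
    "group_wake_time_ci",
]


@dataclass(frozen=True)
class WakeWindow:
    """Daily local-time interval over which at-home time is assessed."""

    start_local: time = time(8, 0)
    end_local: time = time(20, 30)

    def __post_init__(self) -> None:
        if self.end_local <= self.start_local:
            raise ValueError("wake window end must be after start within one day")

    @property
    def start_minute(self) -> int:
        return self.start_local.hour * 60 + self.start_local.minute

    @property
    def end_minute(self) -> int:
        return self.end_local.hour * 60 + self.end_local.minute

    @property
    def minutes_per_day(self) -> int:
        return self.end_minute - self.start_minute


# ---------------------------------------------------------------------------
# Local azimuthal-equidistant projection (spherical)
# ---------------------------------------------------------------------------


def aeqd_forward(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to meters in an AEQD frame centered at (lon0, lat0)."""
    lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def aeqd_inverse(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`aeqd_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            rho > 0,
            np.arcsin(
                np.clip(
                    np.cos(c) * math.sin(phi0) + y * np.sin(c) * math.cos(phi0) / np.where(rho > 0, rho, 1.0),
                    -1.0,
                    1.0,
                )
            ),
            phi0,
        )
        lam = np.where(
            rho > 0,
            lam0
            + np.arctan2(
                x * np.sin(c),
                rho * np.cos(c) * math.cos(phi0) - y * np.sin(c) * math.sin(phi0),
            ),
            lam0,
        )
    return np.degrees(lam), np.degrees(phi)


def buffer_home(footprint: Polygon, distance_m: float, quad_segs: int = 64) -> Polygon:
    """Outward metric buffer of a WGS84 footprint polygon.

    distance 0 returns the footprint unchanged; the result always contains
    the footprint.
    """
    if not footprint.is_valid:
        raise ValueError("invalid footprint polygon")
    if distance_m < 0:
        raise ValueError("buffer distance must be >= 0")
    if distance_m == 0:
        return footprint
    lon0, lat0 = footprint.centroid.x, footprint.centroid.y
    local = shapely.transform(
        footprint,
        lambda coords: np.column_stack(aeqd_forward(coords[:, 0], coords[:, 1], lon0, lat0)),
    )
    buffered = local.buffer(distance_m, quad_segs=quad_segs)
    return shapely.transform(
        buffered,
        lambda coords: np.column_stack(aeqd_inverse(coords[:, 0], coords[:, 1], lon0, lat0)),
    )


def build_home_geometry(
    participant_id: str,
    footprint: Polygon,
    buffers: Sequence[int] = (20, 50, 100),
) -> HomeGeometry:
    return HomeGeometry(
        participant_id,
        footprint,
        {int(b): buffer_home(footprint, float(b)) for b in buffers},
    )


def classify_at_home(
    point: Point | tuple, home: HomeGeometry, buffer: int = 0
) -> bool:
    """True iff the point lies within the selected geofence (boundary inclusive)."""
    if not isinstance(point, Point):
        point = Point(point)
    return bool(home.polygon_at(buffer).covers(point))


# ---------------------------------------------------------------------------
# Minute labeling and proportions
# ---------------------------------------------------------------------------


def at_home_minute_series(
    trajectory: Trajectory,
    home: HomeGeometry,
    buffer: int,
    wake_window: WakeWindow,
    window: StudyWindow,
    method: str = "midpoint",
) -> pd.DataFrame:
    """Label each wake-window minute of the study as home / away / no_data.

    ``method='midpoint'`` classifies the single fix nearest the minute's
    midpoint; ``method='majority'`` takes a majority vote over the minute's
    fixes (ties count as home). Returns a frame with columns ``minute``
    (local tz-aware minute start) and ``label``.
    """
    if method not in ("midpoint", "majority"):
        raise ValueError("method must be 'midpoint' or 'majority'")
    tz = window.tzinfo
    pts = trajectory.points
    mask = (pts["timestamp"] >= window.start) & (pts["timestamp"] < window.end)
    pts = pts.loc[mask]

    # all wake minutes in the window, in local time
    start_local = window.start.astimezone(tz)
    end_local = window.end.astimezone(tz)
    days = pd.date_range(
        start_local.date(), end_local.date(), freq="D", tz=tz, inclusive="both"
    )
    minutes = [
        pd.DatetimeIndex(
            day
            + pd.to_timedelta(
                np.arange(wake_window.start_minute, wake_window.end_minute), unit="min"
            )
        )
        for day in days
    ]
    all_minutes = minutes[0].append(minutes[1:]) if len(minutes) > 1 else minutes[0]
    all_minutes = all_minutes[(all_minutes >= start_local) & (all_minutes < end_local)]

    out = pd.DataFrame({"minute": all_minutes, "label": "no_data"})
    if pts.empty:
        return out

    local_ts = pts["timestamp"].dt.tz_convert(tz)
    minute_floor = local_ts.dt.floor("min")
    sec_in_min = (local_ts - minute_floor).dt.total_seconds()
    tod_min = minute_floor.dt.hour * 60 + minute_floor.dt.minute
    wake_mask = (tod_min >= wake_window.start_minute) & (tod_min < wake_window.end_minute)
    if not wake_mask.any():
        return out

    cand = pd.DataFrame(
        {
            "minute": minute_floor[wake_mask].to_numpy(),
            "dist_mid": (sec_in_min[wake_mask] - 30.0).abs().to_numpy(),
            "lon": pts.loc[wake_mask, "lon"].to_numpy(dtype=float),
            "lat": pts.loc[wake_mask, "lat"].to_numpy(dtype=float),
        }
    )
    geofence = prep(home.polygon_at(buffer))
    at_home = np.fromiter(
        (geofence.intersects(Point(x, y)) for x, y in zip(cand["lon"], cand["lat"])),
        dtype=bool,
        count=len(cand),
    )
    cand["at_home"] = at_home
    if method == "midpoint":
        chosen = cand.loc[cand.groupby("minute")["dist_mid"].idxmin()]
        labels = chosen.set_index("minute")["at_home"].map({True: "home", False: "away"})
    else:
        vote = cand.groupby("minute")["at_home"].mean()
        labels = (vote >= 0.5).map({True: "home", False: "away"})
    labels.index = pd.DatetimeIndex(labels.index).tz_convert(tz)
    out = out.set_index("minute")
    common = labels.index.intersection(out.index)
    out.loc[common, "label"] = labels.loc[common]
    return out.reset_index()


def wake_time_at_home(
    trajectory: Trajectory,
    home: HomeGeometry,
    buffer: int,
    wake_window: WakeWindow,
    window: StudyWindow,
    method: str = "midpoint",
) -> float:
    """Proportion of labeled wake minutes spent at home; NaN when no minute
    could be labeled."""
    series = at_home_minute_series(trajectory, home, buffer, wake_window, window, method)
    n_home = int((series["label"] == "home").sum())
    n_away = int((series["label"] == "away").sum())
    denom = n_home + n_away
    return n_home / denom if denom else float("nan")


def wake_time_cohort(
    trajectories: Mapping[str, Trajectory],
    homes: Mapping[str, HomeGeometry],
    buffers: Sequence[int],
    wake_window: WakeWindow,
    window: StudyWindow,
    method: str = "midpoint",
) -> pd.DataFrame:
    """Per-participant wake-time-at-home proportions at each buffer."""
    rows = []
    for pid, traj in trajectories.items():
        if pid not in homes:
            continue
        for buf in buffers:
            rows.append(
                {
                    "participant_id": pid,
                    "buffer": int(buf),
                    "proportion": wake_time_at_home(
                        traj, homes[pid], int(buf), wake_window, window, method
                    ),
                }
            )
    return pd.DataFrame(rows)


def group_proportion_ci(proportions: Iterable[float]) -> tuple[float, float, float]:
    """Normal-approximation 95% CI for a group mean proportion.

    mean ± 1.96·(sample SD / sqrt(n)), clipped to [0, 1]. With fewer than
    two defined values the CI is undefined (NaN bounds).
    """
    vals = np.asarray([p for p in proportions if not math.isnan(p)], dtype=float)
    if len(vals) == 0:
        return float("nan"), float("nan"), float("nan")
    mean = float(np.mean(vals))
    if len(vals) < 2:
        return mean, float("nan"), float("nan")
    half = 1.96 * float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def group_wake_time_ci(
    proportions: pd.DataFrame,
    metas: Mapping[str, ParticipantMeta],
) -> pd.DataFrame:
    """Group mean and 95% CI per residence / device stratum and buffer.

    Strata are the marginal views (urban, non-urban, android, ios), not a
    cross; input is the output of :func:`wake_time_cohort`.
    """
    frame = proportions.copy()
    frame["residence"] = frame["participant_id"].map(
        lambda pid: metas[pid].residence_setting.value
    )
    frame["device"] = frame["participant_id"].map(lambda pid: metas[pid].device_os.value)
    rows = []
    for kind, col in (("residence", "residence"), ("device", "device")):
        for (stratum, buf), grp in frame.groupby([col, "buffer"], sort=True):
            mean, lo, hi = group_proportion_ci(grp["proportion"])
            rows.append(
                {
                    "stratum_kind": kind,
                    "stratum": stratum,
                    "buffer": int(buf),
                    "n": int(grp["proportion"].notna().sum()),
                    "mean": mean,
                    "lower95": lo,
                    "upper95": hi,
                }
            )
    return pd.DataFrame(rows)
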
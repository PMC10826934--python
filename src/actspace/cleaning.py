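"""Trajectory normalization and outlier filtering.

Cleaning runs in a fixed order mirroring how passively sensed GPS streams
are prepared for activity-space analysis:

1. restrict points to the half-open study window;
2. remove distance-jump artifacts — points whose gap to the previous
   retained fix exceeds ``k`` standard deviations (default k=3) of the
   pooled distance-gap distribution, computed once across the whole cohort;
3. remove impossible-speed artifacts — points implying movement faster
   than ``v_max`` (default 250 m/s, the high end of commercial airplane
   speed) relative to the previous retained fix.

Both outlier filters freeze their threshold before scanning and then make a
single forward pass per trajectory, always dropping the later point of an
offending pair and comparing each candidate against the last *retained*
point. This way one corrupted fix costs exactly one point; the clean fix
after it is re-anchored to the survivor before it, not to the artifact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_types import StudyWindow, Trajectory

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius

__all__ = [
    "EARTH_RADIUS_M",
    "CleaningReport",
    "haversine_distance",
    "haversine_vector",
    "normalize",
    "filter_study_period",
    "consecutive_gaps",
    "pooled_gaps",
    "filter_distance_outliers",
    "filter_speed_outliers",
    "clean_cohort",
]


@dataclass
class CleaningReport:
    """Point accounting for one cleaning run; counts reconcile exactly."""

    n_input: int
    n_outside_window: int
    n_distance_outliers: int
    n_speed_outliers: int
    n_retained: int
    distance_sd: float
    distance_threshold: float
    k: float
    v_max: float

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_outside_window
            - self.n_distance_outliers
            - self.n_speed_outliers
        )
        if self.n_retained != expected:
            raise ValueError(
                f"cleaning counts do not reconcile: retained {self.n_retained} "
                f"!= {expected}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------


def haversine_vector(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in meters on a sphere of radius 6,371,008.8 m."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance between two (lon, lat) pairs, in meters."""
    return float(haversine_vector(*map(np.atleast_1d, (p1[0], p1[1], p2[0], p2[1])))[0])


# ---------------------------------------------------------------------------
# Normalization and window restriction
# ---------------------------------------------------------------------------


def normalize(trajectory: Trajectory) -> Trajectory:
    """Sort by time, collapse duplicates, resolve same-timestamp ties.

    Exact (timestamp, lon, lat) duplicates collapse to one row. When two
    fixes share a timestamp but disagree on position, the one with the
    smaller accuracy radius (more certain) wins. Output timestamps are
    strictly increasing.
    """
    pts = trajectory.points
    # stable sort: timestamp, then accuracy so the most certain fix comes first
    pts = pts.sort_values(["timestamp", "accuracy"], kind="mergesort")
    pts = pts.drop_duplicates(subset=["timestamp", "lon", "lat"], keep="first")
    pts = pts.drop_duplicates(subset=["timestamp"], keep="first")
    return trajectory.replace_points(pts.reset_index(drop=True))


def filter_study_period(trajectory: Trajectory, window: StudyWindow) -> Trajectory:
    """Keep points with window.start <= t < window.end (half-open)."""
    ts = trajectory.points["timestamp"]
    mask = (ts >= window.start) & (ts < window.end)
    out = trajectory.replace_points(trajectory.points.loc[mask].reset_index(drop=True))
    out.window = window
    return out


# ---------------------------------------------------------------------------
# Gap computation
# ---------------------------------------------------------------------------


def consecutive_gaps(trajectory: Trajectory) -> pd.DataFrame:
    """Gaps between consecutive fixes of one participant.

    Returns a frame with columns participant_id, t_prev, t_next, time_gap
    (s), distance_gap (m), speed (m/s); n-1 rows for n points, empty for
    fewer than two points.
    """
    pts = trajectory.points
    cols = ["participant_id", "t_prev", "t_next", "time_gap", "distance_gap", "speed"]
    if len(pts) < 2:
        return pd.DataFrame(columns=cols)
    ts = pts["timestamp"].to_numpy()
    lon = pts["lon"].to_numpy(dtype=float)
    lat = pts["lat"].to_numpy(dtype=float)
    time_gap = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
    dist = haversine_vector(lon[:-1], lat[:-1], lon[1:], lat[1:])
    return pd.DataFrame(
        {
            "participant_id": trajectory.participant_id,
            "t_prev": ts[:-1],
            "t_next": ts[1:],
            "time_gap": time_gap,
            "distance_gap": dist,
            "speed": dist / time_gap,
        }
    )


def pooled_gaps(trajectories: Mapping[str, Trajectory]) -> pd.DataFrame:
    """Concatenate consecutive gaps across all participants."""
    frames = [consecutive_gaps(t) for t in trajectories.values()]
    frames = [f for f in frames if len(f)]
    if not frames:
        return consecutive_gaps(next(iter(trajectories.values()))) if trajectories else pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Outlier filters
# ---------------------------------------------------------------------------


def _survivor_scan(
    trajectory: Trajectory,
    offends: "np.ufunc | callable",
) -> tuple[Trajectory, int]:
    """One forward pass keeping each point iff its gap to the last retained
    point is acceptable; returns the filtered trajectory and removal count.

    ``offends(distance_m, time_gap_s) -> bool`` decides removal of the later
    point. The common case (no removals so far) reuses vectorized
    consecutive distances; after a removal the gap is re-derived against the
    last survivor.
    """
    pts = trajectory.points
    n = len(pts)
    if n < 2:
        return trajectory, 0
    t_s = pts["timestamp"].astype("int64").to_numpy() / 1e9
    lon = pts["lon"].to_numpy(dtype=float)
    lat = pts["lat"].to_numpy(dtype=float)
    d_consec = haversine_vector(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_consec = np.diff(t_s)

    keep = np.ones(n, dtype=bool)
    prev = 0
    removed = 0
    for i in range(1, n):
        if prev == i - 1:
            d, dt = d_consec[i - 1], dt_consec[i - 1]
        else:
            d = haversine_distance((lon[prev], lat[prev]), (lon[i], lat[i]))
            dt = t_s[i] - t_s[prev]
        if offends(d, dt):
            keep[i] = False
            removed += 1
        else:
            prev = i
    if removed == 0:
        return trajectory, 0
    return trajectory.replace_points(pts.loc[keep].reset_index(drop=True)), removed


def filter_distance_outliers(
    trajectories: Mapping[str, Trajectory],
    k: float = 3.0,
    abs_threshold: float | None = None,
) -> tuple[dict[str, Trajectory], int, float, float]:
    """Remove distance-jump points exceeding k·SD of the pooled gap distribution.

    The SD is computed once over all participants' consecutive distance
    gaps; the threshold is frozen before any removal. ``abs_threshold``
    (meters) overrides the k·SD rule to reproduce an externally published
    cut-off. Returns (filtered trajectories, n removed, sd, threshold).
    """
    gaps = pooled_gaps(trajectories)
    if len(gaps) < 2:
        warnings.warn("fewer than 2 gaps in cohort; distance filter is a no-op", stacklevel=2)
        return dict(trajectories), 0, float("nan"), float("inf")
    sd = float(np.std(gaps["distance_gap"].to_numpy(), ddof=1))
    if abs_threshold is not None:
        threshold = float(abs_threshold)
    elif sd > 0:
        threshold = k * sd
    else:
        # degenerate distribution: every gap identical, nothing is an outlier
        threshold = math.inf
    out: dict[str, Trajectory] = {}
    n_removed = 0
    for pid, traj in trajectories.items():
        filtered, removed = _survivor_scan(traj, lambda d, dt: d > threshold)
        out[pid] = filtered
        n_removed += removed
    return out, n_removed, sd, threshold


def filter_speed_outliers(
    trajectories: Mapping[str, Trajectory], v_max: float = 250.0
) -> tuple[dict[str, Trajectory], int]:
    """Remove points implying speed strictly above ``v_max`` m/s.

    Runs on gaps recomputed after the distance filter; a gap at exactly
    ``v_max`` is retained.
    """
    out: dict[str, Trajectory] = {}
    n_removed = 0
    for pid, traj in trajectories.items():
        filtered, removed = _survivor_scan(
            traj, lambda d, dt: dt > 0 and d / dt > v_max
        )
        out[pid] = filtered
        n_removed += removed
    return out, n_removed


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def clean_cohort(
    trajectories: Mapping[str, Trajectory],
    window: StudyWindow,
    k: float = 3.0,
    v_max: float = 250.0,
    abs_distance_threshold: float | None = None,
) -> tuple[dict[str, Trajectory], CleaningReport]:
    """Normalize and clean a cohort: window -> distance filter -> speed filter."""
    n_input = sum(len(t) for t in trajectories.values())
    normalized = {pid: normalize(t) for pid, t in trajectories.items()}
    # duplicate rows collapsed by normalize count as outside no filter bucket;
    # track them inside n_outside_window? They are not window exclusions.
    n_dupes = n_input - sum(len(t) for t in normalized.values())
    windowed = {pid: filter_study_period(t, window) for pid, t in normalized.items()}
    n_after_window = sum(len(t) for t in windowed.values())
    n_outside = (n_input - n_dupes) - n_after_window

    dist_filtered, n_dist, sd, threshold = filter_distance_outliers(
        windowed, k=k, abs_threshold=abs_distance_threshold
    )
    speed_filtered, n_speed = filter_speed_outliers(dist_filtered, v_max=v_max)
    n_retained = sum(len(t) for t in speed_filtered.values())
    report = CleaningReport(
        n_input=n_input - n_dupes,
        n_outside_window=n_outside,
        n_distance_outliers=n_dist,
        n_speed_outliers=n_speed,
        n_retained=n_retained,
        distance_sd=sd,
        distance_threshold=threshold,
        k=k,
        v_max=v_max,
    )
    return speed_filtered, report
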
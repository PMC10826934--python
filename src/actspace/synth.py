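"""Synthetic activity-space cohort generator with ground truth.

Emulates the data a seven-day smartphone sensing study produces: urban and
non-urban participants with home building footprints inside labeled
setting polygons, daily at-home / trip schedules, device-conditional GPS
sampling cadence and accuracy (iOS fixes denser and more accurate than
Android, matching the ordering such studies report), three EMA prompts per
day with truthful answers, day-level dropout, designed GPS-silent EMA
minutes, and injected artifacts (distance jumps and impossible-speed
teleports) with exact labels.

Modeling choices
----------------
* Time gaps and accuracy radii are log-normal (right-skewed, median well
  below mean, as observed in passively sensed GPS).
* Trips are straight-line constant-speed out-and-back excursions to a
  destination 0.2-10 km away; departures, travel legs and dwells are
  aligned to whole minutes so the minute-level ground-truth schedule is
  exact.
* The setting layer is two labeled rectangles; homes and all trip
  destinations stay strictly inside their rectangle, so setting labels are
  recoverable exactly.
* Position noise is an isotropic Gaussian displacement (clipped at 100 m)
  controlled by ``noise_sd_m``; 0 gives noiseless fixes pinned to the true
  path.

Daylight-saving transitions are not modeled; pick a start date whose
seven-day span contains none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .home_time import WakeWindow, build_home_geometry
from .io_types import (
    DeviceOS,
    EmaRecord,
    HomeGeometry,
    ParticipantMeta,
    Setting,
    SettingLayer,
    StudyWindow,
    Trajectory,
)

__all__ = [
    "DeviceModel",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "inject_artifacts",
    "recovery_stats",
]

_M_PER_DEG_LAT = 111_194.9  # mean Earth radius * pi / 180


def _meters_to_deg(dx_m: np.ndarray, dy_m: np.ndarray, lat: float) -> tuple[np.ndarray, np.ndarray]:
    return dx_m / (_M_PER_DEG_LAT * math.cos(math.radians(lat))), dy_m / _M_PER_DEG_LAT


@dataclass(frozen=True)
class DeviceModel:
    """Log-normal sampling cadence and accuracy for one operating system."""

    gap_median_s: float
    gap_sigma: float
    accuracy_median_m: float
    accuracy_sigma: float

    def __post_init__(self) -> None:
        for name in ("gap_median_s", "gap_sigma", "accuracy_median_m", "accuracy_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DeviceModel.{name} must be > 0")


def _default_sampling() -> dict[str, DeviceModel]:
    # iOS denser and more accurate than Android (medians mirror the
    # device contrast reported by smartphone sensing studies)
    return {
        "ios": DeviceModel(2.0, 1.0, 7.0, 0.8),
        "android": DeviceModel(30.0, 1.0, 19.0, 0.8),
    }


@dataclass
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Defaults follow the seven-day urban/non-urban study design: 122 urban
    and 40 non-urban participants, ~62% / ~68% iOS, three EMA prompts per
    day, 08:00-20:30 wake window, 60% of wake time at home.
    """

    n_urban: int = 122
    n_non_urban: int = 40
    ios_fraction_urban: float = 0.623
    ios_fraction_non_urban: float = 0.675
    sampling: dict[str, DeviceModel] = field(default_factory=_default_sampling)
    at_home_fraction: float = 0.60
    trips_per_day: int = 2
    trip_distance_range: tuple[float, float] = (200.0, 10_000.0)
    trip_speed_range: tuple[float, float] = (5.0, 25.0)
    noise_sd_m: float = 10.0
    jump_rate: float = 0.0
    teleport_rate: float = 0.0
    jump_distance_range: tuple[float, float] = (50_000.0, 100_000.0)
    teleport_distance_range: tuple[float, float] = (300.0, 500.0)
    dropout_day_prob: float = 0.05
    ema_per_day: int = 3
    ema_silent_fraction: float = 0.15
    window_days: int = 7
    start_date: str = "2021-04-05"
    timezone: str = "America/New_York"
    footprint_half_m: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_urban < 0 or self.n_non_urban < 0:
            raise ValueError("participant counts must be >= 0")
        if self.n_urban + self.n_non_urban == 0:
            raise ValueError("cohort must contain at least one participant")
        for name in ("ios_fraction_urban", "ios_fraction_non_urban",
                     "at_home_fraction", "ema_silent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CohortConfig.{name}={v} outside [0, 1]")
        for name in ("jump_rate", "teleport_rate", "dropout_day_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"CohortConfig.{name} must be >= 0")
        if self.jump_rate + self.teleport_rate > 0.5:
            raise ValueError("artifact rates too high to place without overlap")
        if self.trips_per_day < 0 or self.window_days < 1 or self.ema_per_day < 0:
            raise ValueError("trips_per_day/ema_per_day must be >= 0, window_days >= 1")
        for key in ("ios", "android"):
            if key not in self.sampling:
                raise ValueError(f"CohortConfig.sampling missing device '{key}'")


@dataclass
class GroundTruth:
    """Labels the generator guarantees about its own output.

    * ``point_truth``: per participant, each emitted clean fix's timestamp
      and true location class (home / away).
    * ``artifacts``: per participant, timestamps and kinds (jump /
      teleport) of every injected artifact point.
    * ``minute_schedule``: per participant, every wake-window minute with
      its true at-home status.
    * ``ema_truth``: true answer for every EMA record (truthful EMA means
      it equals the emitted self-report).
    """

    point_truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    artifacts: dict[str, pd.DataFrame] = field(default_factory=dict)
    minute_schedule: dict[str, pd.DataFrame] = field(default_factory=dict)
    ema_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def schedule_fraction(self, participant_id: str) -> float:
        sched = self.minute_schedule[participant_id]
        return float(sched["at_home"].mean())


@dataclass
class SyntheticCohort:
    trajectories: dict[str, Trajectory]
    homes: dict[str, HomeGeometry]
    setting_layer: SettingLayer
    ema_records: list[EmaRecord]
    metas: dict[str, ParticipantMeta]
    ground_truth: GroundTruth
    window: StudyWindow
    config: CohortConfig


# two labeled rectangles (lon_min, lat_min, lon_max, lat_max)
_URBAN_RECT = (-79.05, 35.85, -78.75, 36.15)
_NON_URBAN_RECT = (-79.70, 35.85, -79.25, 36.15)
_HOME_MARGIN_DEG = 0.02  # keep homes away from rectangle edges
_DEST_MARGIN_DEG = 0.003  # destinations + noise stay strictly inside


def _make_setting_layer() -> SettingLayer:
    return SettingLayer(
        [
            (Setting.urban, box(*_URBAN_RECT)),
            (Setting.non_urban, box(*_NON_URBAN_RECT)),
        ]
    )


def _square_footprint(lon: float, lat: float, half_m: float) -> Polygon:
    dlon, dlat = _meters_to_deg(np.array([half_m]), np.array([half_m]), lat)
    return box(lon - dlon[0], lat - dlat[0], lon + dlon[0], lat + dlat[0])


@dataclass
class _TripLeg:
    t0: float  # seconds from window start
    t1: float
    lon0: float
    lat0: float
    lon1: float
    lat1: float
    at_home: bool


def _sample_destination(
    rng: np.random.Generator,
    home_lon: float,
    home_lat: float,
    dist_m: float,
    rect: tuple[float, float, float, float],
) -> tuple[float, float, float]:
    """Destination at ~dist_m from home, strictly inside the rectangle."""
    lon_min, lat_min, lon_max, lat_max = rect
    m = _DEST_MARGIN_DEG
    d = dist_m
    for _ in range(60):
        az = rng.uniform(0, 2 * math.pi)
        dlon, dlat = _meters_to_deg(d * math.sin(az), d * math.cos(az), home_lat)
        lon, lat = home_lon + dlon, home_lat + dlat
        if lon_min + m < lon < lon_max - m and lat_min + m < lat < lat_max - m:
            return lon, lat, d
        d = max(200.0, d * 0.8)
    raise RuntimeError("could not place trip destination inside setting polygon")


def _build_day_trips(
    rng: np.random.Generator,
    config: CohortConfig,
    wake: WakeWindow,
    day_offset_s: float,
    home_lon: float,
    home_lat: float,
    rect: tuple[float, float, float, float],
) -> tuple[list[_TripLeg], list[tuple[float, float]]]:
    """Whole-minute-aligned trips for one day.

    Returns travel/dwell legs plus (depart, return) second intervals
    (ground-truth away periods).
    """
    wake_minutes = wake.minutes_per_day
    away_total = int(round((1.0 - config.at_home_fraction) * wake_minutes))
    n_trips = config.trips_per_day
    if n_trips == 0 or away_total == 0:
        return [], []
    budgets = [away_total // n_trips] * n_trips
    budgets[0] += away_total - sum(budgets)
    slot = wake_minutes // n_trips
    legs: list[_TripLeg] = []
    away_intervals: list[tuple[float, float]] = []
    for i, budget in enumerate(budgets):
        if budget < 3:
            continue  # need at least out/dwell/back minutes
        travel_min = int(rng.integers(1, max(2, budget // 3)))
        dwell_min = budget - 2 * travel_min
        v = rng.uniform(*config.trip_speed_range)
        dist = float(np.clip(v * travel_min * 60.0, *config.trip_distance_range))
        dest_lon, dest_lat, dist = _sample_destination(rng, home_lon, home_lat, dist, rect)
        slot_start = wake.start_minute + i * slot
        latest = slot_start + slot - budget
        depart_min = int(rng.integers(slot_start, max(slot_start + 1, latest + 1)))
        t0 = day_offset_s + depart_min * 60.0
        t_arrive = t0 + travel_min * 60.0
        t_leave = t_arrive + dwell_min * 60.0
        t_back = t_leave + travel_min * 60.0
        legs.append(_TripLeg(t0, t_arrive, home_lon, home_lat, dest_lon, dest_lat, False))
        legs.append(_TripLeg(t_arrive, t_leave, dest_lon, dest_lat, dest_lon, dest_lat, False))
        legs.append(_TripLeg(t_leave, t_back, dest_lon, dest_lat, home_lon, home_lat, False))
        away_intervals.append((t0, t_back))
    return legs, away_intervals


def _positions_at(
    times: np.ndarray,
    legs: list[_TripLeg],
    home_lon: float,
    home_lat: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True (lon, lat, at_home) at each time; home outside all trip legs."""
    lon = np.full(len(times), home_lon)
    lat = np.full(len(times), home_lat)
    at_home = np.ones(len(times), dtype=bool)
    if not legs:
        return lon, lat, at_home
    starts = np.array([leg.t0 for leg in legs])
    idx = np.searchsorted(starts, times, side="right") - 1
    for k, leg in enumerate(legs):
        sel = (idx == k) & (times >= leg.t0) & (times < leg.t1)
        if not sel.any():
            continue
        frac = (times[sel] - leg.t0) / max(leg.t1 - leg.t0, 1e-9)
        lon[sel] = leg.lon0 + frac * (leg.lon1 - leg.lon0)
        lat[sel] = leg.lat0 + frac * (leg.lat1 - leg.lat0)
        at_home[sel] = False
    return lon, lat, at_home


def inject_artifacts(
    trajectory: Trajectory,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[Trajectory, pd.DataFrame]:
    """Corrupt a clean trajectory with labeled jump and teleport artifacts.

    Jumps replace a fix's coordinates with a location 50-100 km away
    (creating two huge distance gaps); teleports insert an extra fix one
    second after an anchor, 300-500 m away, implying > 250 m/s movement
    but a distance gap far below any plausible jump threshold.
    Returns the corrupted trajectory and a label frame (timestamp, kind).
    """
    pts = trajectory.points
    n = len(pts)
    labels = pd.DataFrame(columns=["timestamp", "kind"])
    if n < 3 or (config.jump_rate == 0 and config.teleport_rate == 0):
        return trajectory, labels
    lat0 = float(pts["lat"].iloc[0])

    out = pts.copy()
    label_rows: list[dict] = []

    # jumps: replace coordinates of interior points
    candidates = np.arange(1, n - 1)
    jump_sel = candidates[rng.random(len(candidates)) < config.jump_rate]
    if len(jump_sel):
        d = rng.uniform(*config.jump_distance_range, size=len(jump_sel))
        az = rng.uniform(0, 2 * math.pi, size=len(jump_sel))
        dlon, dlat = _meters_to_deg(d * np.sin(az), d * np.cos(az), lat0)
        out.iloc[jump_sel, out.columns.get_loc("lon")] += dlon
        out.iloc[jump_sel, out.columns.get_loc("lat")] += dlat
        for i in jump_sel:
            label_rows.append({"timestamp": out["timestamp"].iloc[i], "kind": "jump"})

    # teleports: insert an extra fix 1 s after an anchor when room permits
    ts = out["timestamp"].to_numpy()
    gap_ok = np.zeros(n, dtype=bool)
    gap_ok[:-1] = (ts[1:] - ts[:-1]) > np.timedelta64(2, "s")
    anchors = np.flatnonzero(gap_ok[: n - 1])
    anchors = anchors[~np.isin(anchors, jump_sel)]
    tele_sel = anchors[rng.random(len(anchors)) < config.teleport_rate]
    new_rows = []
    if len(tele_sel):
        d = rng.uniform(*config.teleport_distance_range, size=len(tele_sel))
        az = rng.uniform(0, 2 * math.pi, size=len(tele_sel))
        dlon, dlat = _meters_to_deg(d * np.sin(az), d * np.cos(az), lat0)
        for j, i in enumerate(tele_sel):
            t_new = out["timestamp"].iloc[i] + pd.Timedelta(seconds=1)
            row = {
                "timestamp": t_new,
                "lon": float(out["lon"].iloc[i]) + dlon[j],
                "lat": float(out["lat"].iloc[i]) + dlat[j],
                "accuracy": float(out["accuracy"].iloc[i]),
            }
            new_rows.append(row)
            label_rows.append({"timestamp": t_new, "kind": "teleport"})
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
        out = out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    labels = pd.DataFrame(label_rows, columns=["timestamp", "kind"])
    return trajectory.replace_points(out), labels


def _simulate_participant(
    pid: str,
    meta: ParticipantMeta,
    rng: np.random.Generator,
    config: CohortConfig,
    window: StudyWindow,
    wake: WakeWindow,
    rect: tuple[float, float, float, float],
) -> tuple[Trajectory, HomeGeometry, list[EmaRecord], pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    lon_min, lat_min, lon_max, lat_max = rect
    m = _HOME_MARGIN_DEG
    home_lon = rng.uniform(lon_min + m, lon_max - m)
    home_lat = rng.uniform(lat_min + m, lat_max - m)
    footprint = _square_footprint(home_lon, home_lat, config.footprint_half_m)
    home = build_home_geometry(pid, footprint)

    model = config.sampling[meta.device_os.value]
    span = config.window_days * 86400.0

    legs: list[_TripLeg] = []
    away_by_day: list[list[tuple[float, float]]] = []
    dropout = rng.random(config.window_days) < config.dropout_day_prob
    for d in range(config.window_days):
        day_legs, away = _build_day_trips(
            rng, config, wake, d * 86400.0, home_lon, home_lat, rect
        )
        legs.extend(day_legs)
        away_by_day.append(away)

    # GPS sample times: log-normal inter-fix gaps, per day so dropout can
    # silence whole days
    times_parts = []
    mu = math.log(model.gap_median_s)
    for d in range(config.window_days):
        if dropout[d]:
            continue
        day_len = 86400.0
        expected = int(day_len / (model.gap_median_s * math.exp(model.gap_sigma**2 / 2))) + 10
        gaps = rng.lognormal(mu, model.gap_sigma, size=int(expected * 1.5) + 20)
        t = d * 86400.0 + np.cumsum(gaps)
        t = t[t < (d + 1) * 86400.0]
        while len(gaps) and len(t) and ((d + 1) * 86400.0 - t[-1]) > 60 * model.gap_median_s:
            extra = rng.lognormal(mu, model.gap_sigma, size=200)
            t2 = t[-1] + np.cumsum(extra)
            t = np.concatenate([t, t2[t2 < (d + 1) * 86400.0]])
        times_parts.append(t)
    times = np.concatenate(times_parts) if times_parts else np.array([0.0])
    times = np.sort(times[(times >= 0) & (times < span)])

    lon, lat, at_home = _positions_at(times, legs, home_lon, home_lat)
    accuracy = rng.lognormal(math.log(model.accuracy_median_m), model.accuracy_sigma, len(times))
    if config.noise_sd_m > 0:
        dx = rng.normal(0, config.noise_sd_m, len(times))
        dy = rng.normal(0, config.noise_sd_m, len(times))
        r = np.hypot(dx, dy)
        scale = np.where(r > 100.0, 100.0 / np.maximum(r, 1e-9), 1.0)  # clip at 100 m
        dlon, dlat = _meters_to_deg(dx * scale, dy * scale, home_lat)
        lon = lon + dlon
        lat = lat + dlat

    start = pd.Timestamp(window.start)
    ts = start + pd.to_timedelta(times, unit="s")
    frame = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat, "accuracy": accuracy})

    # EMA: ema_per_day prompts at whole-minute times spread over the wake window
    ema_records: list[EmaRecord] = []
    ema_rows: list[dict] = []
    away_flat = [iv for day in away_by_day for iv in day]
    for d in range(config.window_days):
        third = wake.minutes_per_day // max(config.ema_per_day, 1)
        for k in range(config.ema_per_day):
            minute = wake.start_minute + k * third + int(rng.integers(0, max(third, 1)))
            t_s = d * 86400.0 + minute * 60.0 + 30.0
            truly_home = not any(a <= t_s < b for a, b in away_flat)
            t_abs = start + pd.Timedelta(seconds=t_s)
            answer = "at_home" if truly_home else "not_home"
            ema_records.append(EmaRecord(pid, t_abs.to_pydatetime(), answer))
            ema_rows.append(
                {"participant_id": pid, "timestamp": t_abs, "true_answer": answer}
            )

    # designed GPS-silent EMA minutes
    if config.ema_silent_fraction > 0 and ema_records:
        silent = rng.random(len(ema_records)) < config.ema_silent_fraction
        for flag, rec in zip(silent, ema_records):
            if not flag:
                continue
            t0 = pd.Timestamp(rec.timestamp).floor("min")
            mask = (frame["timestamp"] >= t0) & (frame["timestamp"] < t0 + pd.Timedelta(minutes=1))
            frame = frame.loc[~mask]
        frame = frame.reset_index(drop=True)

    # truth for the surviving fixes (recomputed so it stays aligned)
    secs = (frame["timestamp"] - start).dt.total_seconds().to_numpy()
    _, _, at_home = _positions_at(secs, legs, home_lon, home_lat)
    point_truth = pd.DataFrame(
        {"timestamp": frame["timestamp"].to_numpy(), "at_home": at_home}
    )

    # ground-truth wake-minute schedule
    minute_rows = []
    for d in range(config.window_days):
        mins = np.arange(wake.start_minute, wake.end_minute)
        mids = d * 86400.0 + mins * 60.0 + 30.0
        is_home = np.ones(len(mids), dtype=bool)
        for a, b in away_by_day[d]:
            is_home &= ~((mids >= a) & (mids < b))
        minute_rows.append(
            pd.DataFrame(
                {
                    "minute": start + pd.to_timedelta(d * 86400.0 + mins * 60.0, unit="s"),
                    "at_home": is_home,
                }
            )
        )
    minute_schedule = pd.concat(minute_rows, ignore_index=True)

    traj = Trajectory(pid, frame, window=window, device_os=meta.device_os)
    traj, artifact_labels = inject_artifacts(traj, config, rng)
    return traj, home, ema_records, point_truth, artifact_labels, minute_schedule, ema_rows


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full labeled cohort; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    window = StudyWindow.from_local_date(
        config.start_date, days=config.window_days, timezone=config.timezone
    )
    wake = WakeWindow()
    layer = _make_setting_layer()

    n_total = config.n_urban + config.n_non_urban
    width = max(3, len(str(n_total)))
    truth = GroundTruth()
    trajectories: dict[str, Trajectory] = {}
    homes: dict[str, HomeGeometry] = {}
    metas: dict[str, ParticipantMeta] = {}
    ema_records: list[EmaRecord] = []
    ema_truth_rows: list[dict] = []

    child_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    for i in range(n_total):
        urban = i < config.n_urban
        pid = f"P{i + 1:0{width}d}"
        ruca = int(rng.integers(1, 4)) if urban else int(rng.integers(4, 11))
        ios_frac = config.ios_fraction_urban if urban else config.ios_fraction_non_urban
        device = DeviceOS.ios if rng.random() < ios_frac else DeviceOS.android
        meta = ParticipantMeta(pid, ruca, device)
        rect = _URBAN_RECT if urban else _NON_URBAN_RECT
        prng = np.random.default_rng(int(child_seeds[i]))
        traj, home, emas, point_truth, artifacts, schedule, ema_rows = _simulate_participant(
            pid, meta, prng, config, window, wake, rect
        )
        trajectories[pid] = traj
        homes[pid] = home
        metas[pid] = meta
        ema_records.extend(emas)
        ema_truth_rows.extend(ema_rows)
        truth.point_truth[pid] = point_truth
        truth.artifacts[pid] = artifacts
        truth.minute_schedule[pid] = schedule
    truth.ema_truth = pd.DataFrame(ema_truth_rows)
    return SyntheticCohort(
        trajectories=trajectories,
        homes=homes,
        setting_layer=layer,
        ema_records=ema_records,
        metas=metas,
        ground_truth=truth,
        window=window,
        config=config,
    )


def recovery_stats(
    cohort: SyntheticCohort, cleaned: Mapping[str, Trajectory]
) -> dict[str, float]:
    """Artifact recall and false-removal rate of a cleaning run.

    Compares each cleaned trajectory's surviving timestamps against the
    generator's artifact labels.
    """
    n_art = n_art_removed = n_clean = n_clean_removed = 0
    for pid, traj in cohort.trajectories.items():
        original = traj.points["timestamp"].astype("int64").to_numpy()
        survived = cleaned[pid].points["timestamp"].astype("int64").to_numpy()
        removed_mask = ~np.isin(original, survived)
        art_ts = cohort.ground_truth.artifacts[pid]["timestamp"]
        art = (
            pd.to_datetime(art_ts).astype("int64").to_numpy()
            if len(art_ts)
            else np.array([], dtype="int64")
        )
        is_art = np.isin(original, art)
        n_art += int(is_art.sum())
        n_art_removed += int((is_art & removed_mask).sum())
        n_clean += int((~is_art).sum())
        n_clean_removed += int((~is_art & removed_mask).sum())
    return {
        "n_artifacts": n_art,
        "n_artifacts_removed": n_art_removed,
        "recall": n_art_removed / n_art if n_art else float("nan"),
        "n_clean": n_clean,
        "n_clean_removed": n_clean_removed,
        "false_removal_rate": n_clean_removed / n_clean if n_clean else 0.0,
    }
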
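"""Domain types and file I/O for smartphone GPS activity-space studies.

The study design this package targets: participants carry their own phones
for a seven-day window while an app passively records location fixes
(timestamp, WGS84 lon/lat, accuracy radius), answers three short EMA
surveys per day, and is classified urban / non-urban by the RUCA code of
their county of residence (codes 1-3 urban, 4-10 non-urban).

Timestamps are stored internally in UTC; a per-study IANA timezone converts
to local time wherever calendar-day or wake-window logic applies.

Trajectories hold their points in a pandas DataFrame with columns
``timestamp`` (tz-aware), ``lon``, ``lat``, ``accuracy`` — extra columns
(e.g. ground-truth labels from the simulator) ride along untouched.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.prepared import prep

logger = logging.getLogger("actspace")

POINT_COLUMNS = ["timestamp", "lon", "lat", "accuracy"]

__all__ = [
    "DeviceOS",
    "Setting",
    "GpsPoint",
    "StudyWindow",
    "Trajectory",
    "GapRecord",
    "ParticipantMeta",
    "HomeGeometry",
    "EmaRecord",
    "SettingLayer",
    "SchemaError",
    "classify_residence",
    "assign_point_setting",
    "assign_points_setting",
    "load_gps_csv",
    "write_gps_csv",
    "load_ema_csv",
    "write_ema_csv",
    "load_meta_csv",
    "write_meta_csv",
    "load_setting_layer",
    "write_setting_layer",
    "load_homes",
    "write_homes",
]


class SchemaError(ValueError):
    """A required column is missing or unmappable in an input file."""


class DeviceOS(str, enum.Enum):
    android = "android"
    ios = "ios"


class Setting(str, enum.Enum):
    """Urban / non-urban classification; ``unknown`` only for point labels."""

    urban = "urban"
    non_urban = "non_urban"
    unknown = "unknown"


@dataclass(frozen=True)
class GpsPoint:
    """One sensed location fix.

    ``accuracy`` is the radius in meters of the 68% (one-SD) confidence
    region around the fix; larger values mean less certainty.
    """

    participant_id: str
    timestamp: datetime
    lon: float
    lat: float
    accuracy: float
    device_os: DeviceOS | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if self.accuracy < 0:
            raise ValueError(f"accuracy {self.accuracy} < 0")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")


@dataclass(frozen=True)
class StudyWindow:
    """Half-open study period [start, end) with its local IANA timezone.

    The default span is seven calendar days.
    """

    start: datetime
    end: datetime
    timezone: str = "America/New_York"

    def __post_init__(self) -> None:
        if self.start.tzinfo is None or self.end.tzinfo is None:
            raise ValueError("window bounds must be timezone-aware")
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    @classmethod
    def from_local_date(
        cls, start_date: str, days: int = 7, timezone: str = "America/New_York"
    ) -> "StudyWindow":
        tz = ZoneInfo(timezone)
        start = datetime.fromisoformat(start_date).replace(tzinfo=tz)
        return cls(start=start, end=start + timedelta(days=days), timezone=timezone)

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)

    @property
    def span_seconds(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def total_minutes(self) -> int:
        """Number of whole minutes in the window (7 days -> 10080)."""
        return int(self.span_seconds // 60)


@dataclass
class Trajectory:
    """Time-ordered GPS points of one participant within a study window."""

    participant_id: str
    points: pd.DataFrame
    window: StudyWindow | None = None
    device_os: DeviceOS | None = None

    def __post_init__(self) -> None:
        missing = [c for c in POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise SchemaError(f"trajectory frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_points(
        cls,
        pts: Sequence[GpsPoint],
        window: StudyWindow | None = None,
    ) -> "Trajectory":
        if not pts:
            raise ValueError("cannot build a Trajectory from zero points")
        pid = pts[0].participant_id
        if any(p.participant_id != pid for p in pts):
            raise ValueError("all points must share one participant_id")
        frame = pd.DataFrame(
            {
                "timestamp": pd.to_datetime([p.timestamp for p in pts], utc=True),
                "lon": [p.lon for p in pts],
                "lat": [p.lat for p in pts],
                "accuracy": [p.accuracy for p in pts],
            }
        )
        return cls(pid, frame, window=window, device_os=pts[0].device_os)

    def iter_points(self) -> Iterable[GpsPoint]:
        for row in self.points.itertuples(index=False):
            yield GpsPoint(
                self.participant_id,
                row.timestamp.to_pydatetime(),
                float(row.lon),
                float(row.lat),
                float(row.accuracy),
                self.device_os,
            )

    def replace_points(self, frame: pd.DataFrame) -> "Trajectory":
        return Trajectory(self.participant_id, frame, self.window, self.device_os)


@dataclass(frozen=True)
class GapRecord:
    """Time / distance / speed between two consecutive fixes of one participant."""

    participant_id: str
    t_prev: datetime
    t_next: datetime
    time_gap: float  # seconds, > 0
    distance_gap: float  # meters, >= 0
    speed: float  # m/s

    def __post_init__(self) -> None:
        if self.time_gap <= 0:
            raise ValueError("time_gap must be > 0")
        if self.distance_gap < 0:
            raise ValueError("distance_gap must be >= 0")


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    ruca_code: int
    device_os: DeviceOS
    residence_setting: Setting = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residence_setting", classify_residence(self.ruca_code)
        )


@dataclass
class HomeGeometry:
    """Home building footprint plus nested metric buffers (meters -> polygon).

    Invariant: footprint ⊆ buffer(20) ⊆ buffer(50) ⊆ buffer(100).
    Buffer 0 always resolves to the raw footprint.
    """

    participant_id: str
    footprint: Polygon
    buffers: dict[int, Polygon] = field(default_factory=dict)

    def polygon_at(self, buffer: int) -> Polygon:
        if buffer == 0:
            return self.footprint
        try:
            return self.buffers[buffer]
        except KeyError:
            raise KeyError(
                f"buffer {buffer} m not built for participant {self.participant_id}; "
                f"available: {sorted(self.buffers)}"
            ) from None


@dataclass(frozen=True)
class EmaRecord:
    """One EMA self-report: at-home or not-home at a timestamp."""

    participant_id: str
    timestamp: datetime
    self_report: str  # "at_home" | "not_home"

    def __post_init__(self) -> None:
        if self.self_report not in ("at_home", "not_home"):
            raise ValueError(f"self_report {self.self_report!r} invalid")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")


@dataclass
class SettingLayer:
    """Labeled polygons assigning geographic points to urban / non-urban."""

    polygons: list[tuple[Setting, Polygon]]

    def __post_init__(self) -> None:
        if not self.polygons:
            raise ValueError("setting layer must contain at least one polygon")
        for label, poly in self.polygons:
            if label not in (Setting.urban, Setting.non_urban):
                raise ValueError(f"layer label {label!r} must be urban/non_urban")
            if not poly.is_valid:
                raise ValueError("setting layer polygon is invalid")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_residence(ruca_code: int) -> Setting:
    """Map a RUCA code (1-10) to urban (1-3) or non-urban (4-10)."""
    code = int(ruca_code)
    if not 1 <= code <= 10:
        raise ValueError(f"RUCA code {ruca_code} outside 1-10")
    return Setting.urban if code <= 3 else Setting.non_urban


def assign_point_setting(point: Point | tuple, layer: SettingLayer) -> Setting:
    """Label one point by the first layer polygon containing it.

    Boundary points count as inside (closed polygons). Returns
    ``Setting.unknown`` when no polygon contains the point.
    """
    if not isinstance(point, Point):
        point = Point(point)
    for label, poly in layer.polygons:
        if poly.covers(point):
            return label
    return Setting.unknown


def assign_points_setting(
    lon: np.ndarray, lat: np.ndarray, layer: SettingLayer
) -> np.ndarray:
    """Vectorized setting labels for arrays of coordinates.

    First-containing-polygon rule, identical to :func:`assign_point_setting`.
    """
    out = np.full(len(lon), Setting.unknown.value, dtype=object)
    unresolved = np.ones(len(lon), dtype=bool)
    for label, poly in layer.polygons:
        if not unresolved.any():
            break
        prepared = prep(poly)
        idx = np.flatnonzero(unresolved)
        hits = np.fromiter(
            (prepared.intersects(Point(x, y)) for x, y in zip(lon[idx], lat[idx])),
            dtype=bool,
            count=len(idx),
        )
        out[idx[hits]] = label.value
        unresolved[idx[hits]] = False
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

GPS_REQUIRED = ("participant_id", "timestamp", "lon", "lat", "accuracy")


def _resolve_columns(
    frame: pd.DataFrame, required: Sequence[str], column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename source headers to canonical names; raise on unresolvable columns."""
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return frame


@dataclass
class LoadReport:
    n_rows: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rejected += n
        self.reasons[reason] = self.reasons.get(reason, 0) + n


def load_gps_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    timezone: str = "America/New_York",
    window: StudyWindow | None = None,
) -> tuple[dict[str, Trajectory], LoadReport]:
    """Read a GPS point CSV into one Trajectory per participant.

    Rows with unparseable timestamps or out-of-range coordinates are counted
    in the returned :class:`LoadReport`, never silently dropped. Naive
    timestamps are interpreted in ``timezone``; everything is stored in UTC.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    report = LoadReport(n_rows=len(frame))
    if frame.empty:
        warnings.warn(f"{path}: empty GPS file", stacklevel=2)
        return {}, report
    frame = _resolve_columns(frame, GPS_REQUIRED, column_map)

    ts = pd.to_datetime(frame["timestamp"], errors="coerce", utc=False, format="ISO8601")
    bad_ts = ts.isna()
    if bad_ts.any():
        report.reject("unparseable timestamp", int(bad_ts.sum()))
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(ZoneInfo(timezone), nonexistent="shift_forward", ambiguous=True)
    frame = frame.assign(timestamp=ts.dt.tz_convert("UTC"))

    for col in ("lon", "lat", "accuracy"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad_coord = (
        frame["lat"].isna()
        | frame["lon"].isna()
        | (frame["lat"].abs() > 90)
        | (frame["lon"].abs() > 180)
        | (frame["accuracy"] < 0)
    ) & ~bad_ts
    if bad_coord.any():
        report.reject("invalid coordinates/accuracy", int(bad_coord.sum()))
    ok = ~(bad_ts | bad_coord)
    frame = frame.loc[ok]

    trajectories: dict[str, Trajectory] = {}
    for pid, grp in frame.groupby("participant_id", sort=True):
        dev = None
        if "device_os" in grp.columns:
            dev = DeviceOS(str(grp["device_os"].iloc[0]))
        keep = [c for c in grp.columns if c not in ("participant_id", "device_os")]
        trajectories[str(pid)] = Trajectory(
            str(pid), grp[keep].reset_index(drop=True), window=window, device_os=dev
        )
    if report.n_rejected:
        logger.warning(
            "load_gps_csv(%s): rejected %d of %d rows (%s)",
            path, report.n_rejected, report.n_rows, report.reasons,
        )
    return trajectories, report


def write_gps_csv(path: str | Path, trajectories: Iterable[Trajectory]) -> None:
    frames = []
    for traj in trajectories:
        frame = traj.points.copy()
        frame.insert(0, "participant_id", traj.participant_id)
        if traj.device_os is not None:
            frame["device_os"] = traj.device_os.value
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", *POINT_COLUMNS]
    )
    if "timestamp" in out.columns and len(out):
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


EMA_REQUIRED = ("participant_id", "timestamp", "self_report")


def load_ema_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    timezone: str = "America/New_York",
) -> list[EmaRecord]:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    if frame.empty:
        warnings.warn(f"{path}: empty EMA file", stacklevel=2)
        return []
    frame = _resolve_columns(frame, EMA_REQUIRED, column_map)
    ts = pd.to_datetime(frame["timestamp"], format="ISO8601")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(ZoneInfo(timezone))
    ts = ts.dt.tz_convert("UTC")
    return [
        EmaRecord(str(pid), t.to_pydatetime(), str(ans))
        for pid, t, ans in zip(frame["participant_id"], ts, frame["self_report"])
    ]


def write_ema_csv(path: str | Path, records: Iterable[EmaRecord]) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "timestamp": r.timestamp.isoformat(),
            "self_report": r.self_report,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=EMA_REQUIRED).to_csv(path, index=False)


META_REQUIRED = ("participant_id", "ruca_code", "device_os")


def load_meta_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> dict[str, ParticipantMeta]:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    frame = _resolve_columns(frame, META_REQUIRED, column_map)
    return {
        str(row.participant_id): ParticipantMeta(
            str(row.participant_id), int(row.ruca_code), DeviceOS(str(row.device_os))
        )
        for row in frame.itertuples(index=False)
    }


def write_meta_csv(path: str | Path, metas: Iterable[ParticipantMeta]) -> None:
    rows = [
        {
            "participant_id": m.participant_id,
            "ruca_code": m.ruca_code,
            "device_os": m.device_os.value,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_REQUIRED).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON I/O (FeatureCollections; `label` / `participant_id` properties)
# ---------------------------------------------------------------------------


def load_setting_layer(path: str | Path) -> SettingLayer:
    with open(path) as fh:
        gj = json.load(fh)
    polys = [
        (Setting(feat["properties"]["label"]), shape(feat["geometry"]))
        for feat in gj["features"]
    ]
    return SettingLayer(polys)


def write_setting_layer(path: str | Path, layer: SettingLayer) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label.value},
            "geometry": mapping(poly),
        }
        for label, poly in layer.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def load_homes(path: str | Path) -> dict[str, HomeGeometry]:
    """Read home footprints; buffers are rebuilt downstream, not stored."""
    with open(path) as fh:
        gj = json.load(fh)
    homes: dict[str, HomeGeometry] = {}
    for feat in gj["features"]:
        pid = str(feat["properties"]["participant_id"])
        homes[pid] = HomeGeometry(pid, shape(feat["geometry"]))
    return homes


def write_homes(path: str | Path, homes: Iterable[HomeGeometry]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"participant_id": h.participant_id},
            "geometry": mapping(h.footprint),
        }
        for h in homes
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
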
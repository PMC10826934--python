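"""EMA self-report vs GPS-derived location concordance.

Each EMA answer ("I am at home" / "I am somewhere else") is matched to the
GPS fix recorded in the same whole minute — self-report and sensor clocks
never coincide to the second, so minute granularity with a configurable
tolerance is the operational reading of "the same timestamp". The matched
pairs are cross-tabulated EMA × GPS at-home status per home-buffer size,
with column percentages (columns = EMA answer), per stratum (urban /
non-urban residence, android / ios device — overlapping marginal views).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .home_time import classify_at_home
from .io_types import EmaRecord, HomeGeometry, ParticipantMeta, Trajectory

__all__ = [
    "MatchedPair",
    "ConcordanceTable",
    "match_ema_to_gps",
    "match_cohort",
    "concordance_table",
    "concordance_by_stratum",
    "agreement_summary",
]

STATES = ("at_home", "not_home")


@dataclass(frozen=True)
class MatchedPair:
    participant_id: str
    ema_timestamp: pd.Timestamp
    gps_timestamp: pd.Timestamp
    lon: float
    lat: float
    self_report: str  # at_home | not_home


@dataclass
class ConcordanceTable:
    """2×2 EMA × GPS contingency table with column percentages.

    ``counts[i][j]``: rows follow GPS status, columns EMA status, both in
    the order (at_home, not_home). Column percentages are computed within
    each EMA answer (columns sum to 100%).
    """

    buffer: int
    stratum: str
    counts: np.ndarray
    n_not_matched: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2 (GPS rows × EMA columns)")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def column_pct(self) -> np.ndarray:
        """count / column total × 100; NaN for empty columns."""
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * self.counts / totals, np.nan)
        return pct

    @property
    def at_home_agreement(self) -> float:
        """% of EMA at-home reports with GPS also at home (diagonal)."""
        return float(self.column_pct[0, 0])

    @property
    def not_home_agreement(self) -> float:
        """% of EMA not-home reports with GPS also not home (diagonal)."""
        return float(self.column_pct[1, 1])

    @classmethod
    def from_counts(
        cls,
        buffer: int,
        stratum: str,
        at_home_col: tuple[float, float],
        not_home_col: tuple[float, float],
        n_not_matched: int = 0,
    ) -> "ConcordanceTable":
        """Build from the two EMA columns, each (GPS at-home, GPS not-home)."""
        counts = np.array(
            [[at_home_col[0], not_home_col[0]], [at_home_col[1], not_home_col[1]]],
            dtype=float,
        )
        return cls(buffer=buffer, stratum=stratum, counts=counts, n_not_matched=n_not_matched)

    def as_row(self) -> dict:
        pct = self.column_pct
        return {
            "stratum": self.stratum,
            "buffer": self.buffer,
            "n_ema_at_home_gps_at_home": self.counts[0, 0],
            "n_ema_at_home_gps_not_home": self.counts[1, 0],
            "n_ema_not_home_gps_at_home": self.counts[0, 1],
            "n_ema_not_home_gps_not_home": self.counts[1, 1],
            "pct_ema_at_home_gps_at_home": pct[0, 0],
            "pct_ema_at_home_gps_not_home": pct[1, 0],
            "pct_ema_not_home_gps_at_home": pct[0, 1],
            "pct_ema_not_home_gps_not_home": pct[1, 1],
            "n_not_matched": self.n_not_matched,
        }


def match_ema_to_gps(
    ema_records: Sequence[EmaRecord],
    trajectory: Trajectory,
    tolerance_s: float = 60.0,
) -> tuple[list[MatchedPair], int]:
    """Match each EMA record to the GPS fix sharing its whole minute.

    When several fixes share the minute, the one nearest the EMA second
    wins; the fix must also lie within ``tolerance_s`` of the EMA
    timestamp. Returns (matched pairs, count of unmatched EMA records).
    """
    pts = trajectory.points
    matched: list[MatchedPair] = []
    n_unmatched = 0
    if pts.empty:
        return [], len(ema_records)
    ts = pts["timestamp"]
    minute = ts.dt.floor("min")
    for rec in ema_records:
        ema_ts = pd.Timestamp(rec.timestamp)
        ema_minute = ema_ts.floor("min")
        in_minute = minute == ema_minute
        if in_minute.any():
            delta = (ts[in_minute] - ema_ts).dt.total_seconds().abs()
            best = delta.idxmin()
            if delta.loc[best] <= tolerance_s:
                row = pts.loc[best]
                matched.append(
                    MatchedPair(
                        rec.participant_id,
                        ema_ts,
                        row["timestamp"],
                        float(row["lon"]),
                        float(row["lat"]),
                        rec.self_report,
                    )
                )
                continue
        n_unmatched += 1
    return matched, n_unmatched


def match_cohort(
    ema_records: Sequence[EmaRecord],
    trajectories: Mapping[str, Trajectory],
    tolerance_s: float = 60.0,
) -> tuple[list[MatchedPair], dict[str, int]]:
    """Match every participant's EMA records; unmatched counts per participant."""
    by_pid: dict[str, list[EmaRecord]] = {}
    for rec in ema_records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    matched: list[MatchedPair] = []
    unmatched: dict[str, int] = {}
    for pid, recs in by_pid.items():
        traj = trajectories.get(pid)
        if traj is None:
            unmatched[pid] = len(recs)
            continue
        pairs, n_un = match_ema_to_gps(recs, traj, tolerance_s)
        matched.extend(pairs)
        unmatched[pid] = n_un
    return matched, unmatched


def concordance_table(
    matched_pairs: Iterable[MatchedPair],
    homes: Mapping[str, HomeGeometry],
    buffer: int,
    stratum: str = "all",
    n_not_matched: int = 0,
) -> ConcordanceTable:
    """Cross-tabulate EMA answers against GPS at-home status at one buffer."""
    counts = np.zeros((2, 2), dtype=float)
    for pair in matched_pairs:
        gps_home = classify_at_home(
            (pair.lon, pair.lat), homes[pair.participant_id], buffer
        )
        i = 0 if gps_home else 1
        j = 0 if pair.self_report == "at_home" else 1
        counts[i, j] += 1
    return ConcordanceTable(buffer=buffer, stratum=stratum, counts=counts, n_not_matched=n_not_matched)


def concordance_by_stratum(
    matched_pairs: Sequence[MatchedPair],
    homes: Mapping[str, HomeGeometry],
    metas: Mapping[str, ParticipantMeta],
    buffers: Sequence[int],
    unmatched: Mapping[str, int] | None = None,
) -> list[ConcordanceTable]:
    """Tables for every buffer × stratum (residence and device margins)."""
    unmatched = unmatched or {}

    def stratum_of(pid: str, kind: str) -> str:
        meta = metas[pid]
        return meta.residence_setting.value if kind == "residence" else meta.device_os.value

    tables: list[ConcordanceTable] = []
    for buf in buffers:
        for kind in ("residence", "device"):
            strata = sorted({stratum_of(pid, kind) for pid in metas})
            for stratum in strata:
                pids = {pid for pid in metas if stratum_of(pid, kind) == stratum}
                pairs = [p for p in matched_pairs if p.participant_id in pids]
                n_un = sum(unmatched.get(pid, 0) for pid in pids)
                tables.append(
                    concordance_table(pairs, homes, int(buf), stratum, n_un)
                )
    return tables


def agreement_summary(tables: Sequence[ConcordanceTable]) -> pd.DataFrame:
    """Per-buffer min / mean diagonal agreement across strata.

    Diagonals are the at-home and not-home column agreements; NaN cells
    (empty columns) are ignored.
    """
    if not tables:
        raise ValueError("need at least one concordance table")
    def _nanstat(values: np.ndarray, fn) -> float:
        return float(fn(values)) if not np.isnan(values).all() else float("nan")

    rows = []
    for buf in sorted({t.buffer for t in tables}):
        sub = [t for t in tables if t.buffer == buf]
        at_home = np.array([t.at_home_agreement for t in sub], dtype=float)
        not_home = np.array([t.not_home_agreement for t in sub], dtype=float)
        rows.append(
            {
                "buffer": buf,
                "min_at_home_agreement": _nanstat(at_home, np.nanmin),
                "mean_at_home_agreement": _nanstat(at_home, np.nanmean),
                "min_not_home_agreement": _nanstat(not_home, np.nanmin),
                "mean_not_home_agreement": _nanstat(not_home, np.nanmean),
            }
        )
    return pd.DataFrame(rows)
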
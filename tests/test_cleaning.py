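"""Normalization, gap computation, and the distance / speed outlier filters."""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actspace.cleaning import (
    EARTH_RADIUS_M,
    clean_cohort,
    consecutive_gaps,
    filter_distance_outliers,
    filter_speed_outliers,
    filter_study_period,
    haversine_distance,
    normalize,
)
from actspace.io_types import StudyWindow, Trajectory

UTC = timezone.utc


def traj_from_rows(rows, pid="p1"):
    """rows: (iso_ts, lon, lat, accuracy)"""
    frame = pd.DataFrame(rows, columns=["timestamp", "lon", "lat", "accuracy"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
    return Trajectory(pid, frame)


def spherical_law_of_cosines(lon1, lat1, lon2, lat2):
    """Independent distance oracle: d = R·arccos(sinφ1 sinφ2 + cosφ1 cosφ2 cosΔλ)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_M * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_distance((-79.0, 36.0), (-79.0, 36.0)) == 0.0

    def test_one_degree_latitude_closed_form(self):
        # 1° of latitude on a sphere = R·π/180
        d = haversine_distance((0.0, 0.0), (0.0, 1.0))
        assert d == pytest.approx(EARTH_RADIUS_M * math.pi / 180.0, rel=1e-12)

    def test_symmetry(self):
        a, b = (-79.1, 36.2), (-78.7, 35.9)
        assert haversine_distance(a, b) == pytest.approx(haversine_distance(b, a))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        lon1=st.floats(-179, 179),
        lat1=st.floats(-80, 80),
        lon2=st.floats(-179, 179),
        lat2=st.floats(-80, 80),
    )
    def test_matches_law_of_cosines_oracle(self, lon1, lat1, lon2, lat2):
        d = haversine_distance((lon1, lat1), (lon2, lat2))
        oracle = spherical_law_of_cosines(lon1, lat1, lon2, lat2)
        # the oracle itself carries an absolute roundoff floor of
        # ~R·sqrt(2·eps) ≈ 0.1 m for near-coincident points
        assert d == pytest.approx(oracle, rel=1e-6, abs=0.2)


class TestNormalize:
    def test_sorts_by_timestamp(self):
        t = traj_from_rows(
            [
                ("2021-04-05T10:02:00", -79.0, 36.0, 5),
                ("2021-04-05T10:00:00", -79.0, 36.0, 5),
                ("2021-04-05T10:01:00", -79.0, 36.0, 5),
            ]
        )
        out = normalize(t)
        assert out.points["timestamp"].is_monotonic_increasing

    def test_exact_duplicates_collapse(self):
        t = traj_from_rows(
            [
                ("2021-04-05T10:00:00", -79.0, 36.0, 5),
                ("2021-04-05T10:00:00", -79.0, 36.0, 5),
            ]
        )
        assert len(normalize(t)) == 1

    def test_same_timestamp_keeps_more_certain_fix(self):
        t = traj_from_rows(
            [
                ("2021-04-05T10:00:00", -79.5, 36.5, 50.0),
                ("2021-04-05T10:00:00", -79.0, 36.0, 5.0),
            ]
        )
        out = normalize(t)
        assert len(out) == 1
        assert out.points["accuracy"].iloc[0] == 5.0


class TestStudyPeriodFilter:
    def test_half_open_boundaries(self):
        w = StudyWindow(
            datetime(2021, 4, 5, tzinfo=UTC), datetime(2021, 4, 12, tzinfo=UTC), "UTC"
        )
        t = traj_from_rows(
            [
                ("2021-04-05T00:00:00", -79.0, 36.0, 5),  # exactly start: kept
                ("2021-04-08T12:00:00", -79.0, 36.0, 5),
                ("2021-04-12T00:00:00", -79.0, 36.0, 5),  # exactly end: dropped
                ("2021-04-04T23:59:59", -79.0, 36.0, 5),  # before start: dropped
            ]
        )
        out = filter_study_period(normalize(t), w)
        assert len(out) == 2
        assert out.points["timestamp"].min() == pd.Timestamp("2021-04-05", tz="UTC")


class TestConsecutiveGaps:
    def test_two_point_arithmetic(self):
        # ~30 m apart (0.00027° lat ≈ 30 m), 10 s apart -> ~3 m/s
        dlat = 30.0 / (EARTH_RADIUS_M * math.pi / 180.0)
        t = traj_from_rows(
            [
                ("2021-04-05T10:00:00", -79.0, 36.0, 5),
                ("2021-04-05T10:00:10", -79.0, 36.0 + dlat, 5),
            ]
        )
        gaps = consecutive_gaps(t)
        assert len(gaps) == 1
        assert gaps["time_gap"].iloc[0] == 10.0
        assert gaps["distance_gap"].iloc[0] == pytest.approx(30.0, rel=1e-6)
        assert gaps["speed"].iloc[0] == pytest.approx(3.0, rel=1e-6)

    def test_collinear_distances_additive(self):
        dlat = 100.0 / (EARTH_RADIUS_M * math.pi / 180.0)
        t = traj_from_rows(
            [
                ("2021-04-05T10:00:00", -79.0, 36.0, 5),
                ("2021-04-05T10:01:00", -79.0, 36.0 + dlat, 5),
                ("2021-04-05T10:02:00", -79.0, 36.0 + 2 * dlat, 5),
            ]
        )
        gaps = consecutive_gaps(t)
        assert len(gaps) == 2
        total = gaps["distance_gap"].sum()
        end_to_end = haversine_distance((-79.0, 36.0), (-79.0, 36.0 + 2 * dlat))
        assert total == pytest.approx(end_to_end, rel=1e-9)

    def test_fixed_cadence_gaps(self):
        rows = [
            (f"2021-04-05T10:{m:02d}:00", -79.0, 36.0 + m * 1e-5, 5) for m in range(10)
        ]
        gaps = consecutive_gaps(traj_from_rows(rows))
        assert (gaps["time_gap"] == 60.0).all()

    def test_single_point_empty(self):
        t = traj_from_rows([("2021-04-05T10:00:00", -79.0, 36.0, 5)])
        assert consecutive_gaps(t).empty


class TestDistanceFilter:
    def test_degenerate_all_equal_gaps_no_removal(self):
        rows = [(f"2021-04-05T10:{m:02d}:00", -79.0, 36.0, 5) for m in range(5)]
        # identical positions -> every gap 0 -> SD 0 -> guard disables filter
        trajs = {"p1": traj_from_rows(rows)}
        out, n_removed, sd, threshold = filter_distance_outliers(trajs)
        assert n_removed == 0
        assert sd == 0.0
        assert math.isinf(threshold)

    def test_single_injected_jump_removed_exactly(self):
        dlat = 10.0 / (EARTH_RADIUS_M * math.pi / 180.0)
        base = datetime(2021, 4, 5, 10, 0, 0, tzinfo=UTC)
        rows = [
            ((base + timedelta(minutes=m)).isoformat(), -79.0, 36.0 + m * dlat, 5)
            for m in range(1000)
        ]
        # one 50 km jump at index 500
        jump_dlat = 50_000.0 / (EARTH_RADIUS_M * math.pi / 180.0)
        rows[500] = (rows[500][0], -79.0, rows[500][2] + jump_dlat, 5)
        trajs = {"p1": traj_from_rows(rows)}
        out, n_removed, sd, threshold = filter_distance_outliers(trajs)
        assert n_removed == 1
        kept = out["p1"].points
        assert len(kept) == 999
        # the landing point of the jump is gone; its neighbors survive
        assert not np.isclose(kept["lat"], 36.0 + 500 * dlat + jump_dlat).any()

    def test_fewer_than_two_gaps_warns_and_noop(self):
        trajs = {"p1": traj_from_rows([("2021-04-05T10:00:00", -79.0, 36.0, 5)])}
        with pytest.warns(UserWarning):
            out, n_removed, _, _ = filter_distance_outliers(trajs)
        assert n_removed == 0


class TestSpeedFilter:
    def _pair(self, dist_m, dt_s):
        dlat = dist_m / (EARTH_RADIUS_M * math.pi / 180.0)
        t0 = datetime(2021, 4, 5, 10, 0, 0, tzinfo=UTC)
        return traj_from_rows(
            [
                (t0.isoformat(), -79.0, 36.0, 5),
                ((t0 + timedelta(seconds=dt_s)).isoformat(), -79.0, 36.0 + dlat, 5),
            ]
        )

    def test_speed_above_threshold_removes_later_point(self):
        out, n = filter_speed_outliers({"p1": self._pair(300.0, 1)})
        assert n == 1
        assert len(out["p1"]) == 1

    def test_exactly_at_threshold_retained(self):
        # strict inequality: 250 m in 1 s is kept
        out, n = filter_speed_outliers({"p1": self._pair(249.999, 1)})
        assert n == 0
        assert len(out["p1"]) == 2


class TestPipeline:
    def test_report_counts_reconcile(self, artifact_cohort):
        cleaned, report = clean_cohort(
            artifact_cohort.trajectories, artifact_cohort.window
        )
        assert report.n_retained == sum(len(t) for t in cleaned.values())
        assert (
            report.n_input
            - report.n_outside_window
            - report.n_distance_outliers
            - report.n_speed_outliers
            == report.n_retained
        )
        assert report.distance_threshold == pytest.approx(3.0 * report.distance_sd)

    def test_second_pass_with_frozen_threshold_removes_nothing(self, artifact_cohort):
        cleaned, report = clean_cohort(
            artifact_cohort.trajectories, artifact_cohort.window
        )
        again, report2 = clean_cohort(
            cleaned,
            artifact_cohort.window,
            abs_distance_threshold=report.distance_threshold,
        )
        assert report2.n_distance_outliers == 0
        assert report2.n_speed_outliers == 0

    def test_speed_filter_idempotent(self, artifact_cohort):
        """The speed threshold is absolute, so re-running it removes nothing
        (the SD-based distance threshold is only stable when frozen)."""
        cleaned, _ = clean_cohort(artifact_cohort.trajectories, artifact_cohort.window)
        _, n_removed = filter_speed_outliers(cleaned)
        assert n_removed == 0

    def test_surviving_points_unmutated_and_ordered(self, artifact_cohort):
        cleaned, _ = clean_cohort(artifact_cohort.trajectories, artifact_cohort.window)
        for pid, traj in cleaned.items():
            orig = artifact_cohort.trajectories[pid].points
            merged = traj.points.merge(
                orig, on=["timestamp"], suffixes=("", "_orig"), how="left"
            )
            assert np.allclose(merged["lon"], merged["lon_orig"])
            assert np.allclose(merged["lat"], merged["lat_orig"])
            assert traj.points["timestamp"].is_monotonic_increasing
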
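"""Participant-level quality metrics and the grouped / point-level tables."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from actspace.io_types import DeviceOS, ParticipantMeta, StudyWindow, Trajectory
from actspace.quality import (
    OutlierThresholds,
    group_summary,
    outlier_incidence,
    participant_quality_summary,
    participation_days,
    temporal_coverage,
)

UTC = timezone.utc
WINDOW = StudyWindow(
    datetime(2021, 4, 5, tzinfo=UTC), datetime(2021, 4, 12, tzinfo=UTC), "UTC"
)


def traj(timestamps, pid="p1", lon=-79.0, lat=36.0, accuracy=5.0):
    frame = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(timestamps, utc=True),
            "lon": lon,
            "lat": lat,
            "accuracy": accuracy,
        }
    )
    return Trajectory(pid, frame)


class TestParticipationDays:
    def test_seven_distinct_dates(self):
        t = traj([f"2021-04-{5 + d:02d}T12:00:00" for d in range(7)])
        assert participation_days(t, WINDOW) == 7

    def test_all_points_one_date(self):
        t = traj([f"2021-04-05T{h:02d}:00:00" for h in range(10)])
        assert participation_days(t, WINDOW) == 1

    def test_empty_trajectory(self):
        t = traj(["2021-04-05T00:00:00"])
        t.points = t.points.iloc[:0]
        assert participation_days(t, WINDOW) == 0

    def test_dropout_days_reduce_count(self, noisy_cohort):
        """Generator dropout silences whole days; counts must reflect it."""
        truth_days = {}
        for pid, t in noisy_cohort.trajectories.items():
            local = t.points["timestamp"].dt.tz_convert(noisy_cohort.window.timezone)
            truth_days[pid] = local.dt.normalize().nunique()
        for pid, t in noisy_cohort.trajectories.items():
            assert participation_days(t, noisy_cohort.window) == truth_days[pid]
        assert max(truth_days.values()) <= 7


class TestTemporalCoverage:
    def test_point_every_minute_gives_full_coverage(self):
        minutes = pd.date_range(WINDOW.start, WINDOW.end, freq="min", inclusive="left")
        t = traj(list(minutes))
        assert temporal_coverage(t, WINDOW) == 1.0

    def test_one_full_day_of_seven(self):
        minutes = pd.date_range(
            "2021-04-06T00:00:00Z", "2021-04-07T00:00:00Z", freq="min", inclusive="left"
        )
        t = traj(list(minutes))
        assert temporal_coverage(t, WINDOW) == pytest.approx(1440 / 10080)

    def test_empty_trajectory_zero(self):
        t = traj(["2021-04-05T00:00:00"])
        t.points = t.points.iloc[:0]
        assert temporal_coverage(t, WINDOW) == 0.0

    def test_many_points_same_minute_count_once(self):
        t = traj([f"2021-04-05T10:00:{s:02d}" for s in range(30)])
        assert temporal_coverage(t, WINDOW) == pytest.approx(1 / 10080)


class TestParticipantSummary:
    def test_equally_spaced_points(self):
        t = traj(
            ["2021-04-05T10:00:00", "2021-04-05T10:01:00", "2021-04-05T10:02:00"]
        )
        q = participant_quality_summary(t, WINDOW)
        assert q.time_gap_stats.mean == 60.0
        assert q.time_gap_stats.median == 60.0
        assert q.time_gap_stats.sd == 0.0
        assert q.n_points == 3

    def test_constant_accuracy(self):
        t = traj(["2021-04-05T10:00:00", "2021-04-05T10:01:00", "2021-04-05T10:02:00"])
        q = participant_quality_summary(t, WINDOW)
        assert (q.accuracy_stats.mean, q.accuracy_stats.sd, q.accuracy_stats.median) == (5.0, 0.0, 5.0)

    def test_under_two_gaps_flagged_undefined(self):
        t = traj(["2021-04-05T10:00:00", "2021-04-05T10:01:00"])
        q = participant_quality_summary(t, WINDOW)
        assert not q.defined
        assert np.isnan(q.time_gap_stats.mean)
        assert q.n_points == 2  # counts still reported

    def test_device_cadence_ordering(self, noisy_cohort):
        """iOS samples denser than Android: mean participant time gap lower."""
        window = noisy_cohort.window
        by_dev = {"ios": [], "android": []}
        for pid, t in noisy_cohort.trajectories.items():
            q = participant_quality_summary(t, window)
            by_dev[noisy_cohort.metas[pid].device_os.value].append(q.time_gap_stats.mean)
        assert np.mean(by_dev["ios"]) < np.mean(by_dev["android"])


class TestGroupSummary:
    def _qualities(self, cohort):
        return {
            pid: participant_quality_summary(t, cohort.window)
            for pid, t in cohort.trajectories.items()
        }

    def test_single_participant_group_equals_value(self):
        t = traj(["2021-04-05T10:00:00", "2021-04-05T10:01:00", "2021-04-05T10:02:00"])
        q = participant_quality_summary(t, WINDOW)
        metas = {"p1": ParticipantMeta("p1", 2, DeviceOS.ios)}
        table = group_summary({"p1": q}, metas, "residence")
        row = table[(table["group"] == "urban") & (table["metric"] == "time_gap_mean")]
        assert row["mean"].iloc[0] == 60.0

    def test_two_participant_mean_and_median(self):
        t1 = traj(["2021-04-05T10:00:00", "2021-04-05T10:01:00", "2021-04-05T10:02:00"], pid="a")
        t2 = traj(["2021-04-05T10:00:00", "2021-04-05T10:02:00", "2021-04-05T10:04:00"], pid="b")
        qs = {
            "a": participant_quality_summary(t1, WINDOW),
            "b": participant_quality_summary(t2, WINDOW),
        }
        metas = {
            "a": ParticipantMeta("a", 1, DeviceOS.ios),
            "b": ParticipantMeta("b", 2, DeviceOS.android),
        }
        table = group_summary(qs, metas, "residence")
        row = table[(table["group"] == "urban") & (table["metric"] == "time_gap_mean")]
        assert row["mean"].iloc[0] == 90.0  # mean of 60 and 120
        assert row["median"].iloc[0] == 90.0
        ios = table[(table["group"] == "urban") & (table["metric"] == "pct_ios_users")]
        assert ios["mean"].iloc[0] == 50.0

    def test_design_counts_recovered(self, noisy_cohort):
        qs = self._qualities(noisy_cohort)
        table = group_summary(qs, noisy_cohort.metas, "residence")
        n = table[table["metric"] == "n_participants"].set_index("group")["mean"]
        assert n["urban"] == noisy_cohort.config.n_urban
        assert n["non_urban"] == noisy_cohort.config.n_non_urban


class TestOutlierIncidence:
    def test_no_outliers_all_percentages_zero(self):
        """Gaps and accuracies all under the cut-offs yield 0% everywhere."""
        from shapely.geometry import box
        from actspace.io_types import Setting, SettingLayer

        stamps = [f"2021-04-05T10:{m:02d}:00" for m in range(60)]
        t = traj(stamps, accuracy=20.0)  # 60 s gaps, ~0 m apart, 20 m accuracy
        metas = {"p1": ParticipantMeta("p1", 1, DeviceOS.ios)}
        layer = SettingLayer([(Setting.urban, box(-80, 35, -78, 37))])
        table = outlier_incidence({"p1": t}, metas, layer, OutlierThresholds())
        cell = table[table["n_points"] > 0]
        assert (cell["pct_time_gap_outlier"] == 0).all()
        assert (cell["pct_distance_gap_outlier"] == 0).all()
        assert (cell["pct_accuracy_outlier"] == 0).all()

    def test_single_long_gap_share(self):
        # one 2 h gap among 99 sub-minute gaps -> 1% share
        stamps = [f"2021-04-05T10:{m // 60:02d}:{m % 60:02d}" for m in range(99)]
        stamps.append("2021-04-05T13:00:00")
        t = traj(stamps)
        metas = {"p1": ParticipantMeta("p1", 1, DeviceOS.ios)}
        from shapely.geometry import box
        from actspace.io_types import Setting, SettingLayer

        layer = SettingLayer([(Setting.urban, box(-80, 35, -78, 37))])
        table = outlier_incidence({"p1": t}, metas, layer, OutlierThresholds())
        cell = table[(table["residence"] == "urban") & (table["setting"] == "urban")]
        assert cell["pct_time_gap_outlier"].iloc[0] == pytest.approx(100.0 / 99)

    def test_location_percentages_sum_to_100(self, noisy_cohort):
        table = outlier_incidence(
            noisy_cohort.trajectories,
            noisy_cohort.metas,
            noisy_cohort.setting_layer,
            OutlierThresholds(),
        )
        sums = table.groupby("residence")["pct_points_by_location"].sum()
        assert np.allclose(sums, 100.0)

    def test_medians_below_means_on_skewed_gaps(self, noisy_cohort):
        """Log-normal gap draws are right-skewed: pooled median < mean."""
        table = outlier_incidence(
            noisy_cohort.trajectories,
            noisy_cohort.metas,
            noisy_cohort.setting_layer,
            OutlierThresholds(),
        )
        populated = table[table["n_points"] > 100]
        assert (populated["time_gap_median"] <= populated["time_gap_mean"]).all()
        assert (populated["accuracy_median"] <= populated["accuracy_mean"]).all()

    def test_device_stratified_tables(self, noisy_cohort):
        table = outlier_incidence(
            noisy_cohort.trajectories,
            noisy_cohort.metas,
            noisy_cohort.setting_layer,
            OutlierThresholds(),
            stratify_by_device=True,
        )
        assert "device" in table.columns
        sums = (
            table.dropna(subset=["pct_points_by_location"])
            .groupby(["residence", "device"])["pct_points_by_location"]
            .sum()
        )
        # strata that exist in the cohort must each account for all points
        populated = table[table["n_points"] > 0][["residence", "device"]].drop_duplicates()
        for _, row in populated.iterrows():
            assert sums[(row["residence"], row["device"])] == pytest.approx(100.0)

    def test_participant_vs_point_level_pooling_differ(self, noisy_cohort):
        """Cohort tables use participant-level statistics; pooling all points
        gives a different number — both paths must exist and disagree."""
        qs = {
            pid: participant_quality_summary(t, noisy_cohort.window)
            for pid, t in noisy_cohort.trajectories.items()
        }
        table = group_summary(qs, noisy_cohort.metas, "residence")
        participant_level = table[
            (table["group"] == "urban") & (table["metric"] == "time_gap_mean")
        ]["mean"].iloc[0]
        point_table = outlier_incidence(
            noisy_cohort.trajectories,
            noisy_cohort.metas,
            noisy_cohort.setting_layer,
            OutlierThresholds(),
        )
        cell = point_table[
            (point_table["residence"] == "urban") & (point_table["setting"] == "urban")
        ]
        point_level = cell["time_gap_mean"].iloc[0]
        assert participant_level != pytest.approx(point_level, rel=1e-6)
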
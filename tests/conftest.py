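"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import pytest

from actspace.synth import CohortConfig, DeviceModel, simulate_cohort


def small_sampling(ios_median: float = 10.0, android_median: float = 40.0):
    """Coarser-than-default cadences to keep test cohorts small; the iOS <
    Android ordering of the study design is preserved."""
    return {
        "ios": DeviceModel(ios_median, 0.8, 7.0, 0.8),
        "android": DeviceModel(android_median, 0.8, 19.0, 0.8),
    }


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless, artifact-free cohort: fixes sit exactly on the true path."""
    cfg = CohortConfig(
        n_urban=3,
        n_non_urban=2,
        seed=11,
        noise_sd_m=0.0,
        jump_rate=0.0,
        teleport_rate=0.0,
        dropout_day_prob=0.0,
        ema_silent_fraction=0.0,
        sampling=small_sampling(5.0, 20.0),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Realistic small cohort: 10 m GPS noise, dropout, silent EMA minutes."""
    cfg = CohortConfig(
        n_urban=6,
        n_non_urban=4,
        seed=23,
        noise_sd_m=10.0,
        jump_rate=0.0,
        teleport_rate=0.0,
        dropout_day_prob=0.05,
        ema_silent_fraction=0.15,
        sampling=small_sampling(),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def artifact_cohort():
    """Cohort with labeled distance-jump and teleport artifacts injected."""
    cfg = CohortConfig(
        n_urban=6,
        n_non_urban=4,
        seed=42,
        noise_sd_m=10.0,
        jump_rate=0.01,
        teleport_rate=0.002,
        dropout_day_prob=0.05,
        sampling=small_sampling(),
    )
    return simulate_cohort(cfg)
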
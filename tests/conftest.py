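"""Shared fixtures: small simulated recordings and cohorts."""

import numpy as np
import pytest

from gripscreen.synthetic_data import (
    DEFAULT_PROFILES,
    SimConfig,
    default_geometry,
    simulate_cohort,
    simulate_recording,
)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def control_recording(geometry):
    return simulate_recording(DEFAULT_PROFILES["control"], geometry,
                              "ctrl001", "control", "right", 1, seed=12345)


@pytest.fixture(scope="session")
def cm_recording(geometry):
    return simulate_recording(DEFAULT_PROFILES["CM"], geometry,
                              "CM001", "CM", "left", 2, seed=54321)


@pytest.fixture(scope="session")
def small_cohort():
    """5 participants per group, all three groups (60 recordings)."""
    config = SimConfig(n_per_group={"CM": 5, "CTS": 5, "control": 5}, seed=7)
    return simulate_cohort(config)
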
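"""Shared fixtures: simulated sessions and trained systems, generated once."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from orthobci.calibration import ScheduleConfig, TrainingConfig, \
    build_schedule, train_system
from orthobci.simulate import SimulationParams, simulate_calibration

#: Reduced calibration geometry for tests that only need statistics, not the
#: full 320 s session (4 runs x 15 rounds -> 60 target / 300 non-target).
SMALL_SCHEDULE = ScheduleConfig(n_runs=4, rounds_per_run=15)

NULL_PARAMS = replace(SimulationParams(), erp_amplitude=0.0,
                      early_negativity_amplitude=0.0)


@pytest.fixture(scope="session")
def default_calibration():
    """Full default-geometry calibration session, simulator defaults, seed 1."""
    schedule = build_schedule(1)
    return simulate_calibration(schedule, SimulationParams(), seed=1)


@pytest.fixture(scope="session")
def trained_system(default_calibration):
    """System trained on the default calibration (CV report deferred)."""
    return train_system(default_calibration.recording,
                        TrainingConfig(compute_cv=False))


@pytest.fixture(scope="session")
def null_calibration():
    """Full-geometry calibration with no evoked component (chance floor)."""
    schedule = build_schedule(2)
    return simulate_calibration(schedule, NULL_PARAMS, seed=2)


@pytest.fixture(scope="session")
def small_calibration():
    """Reduced-geometry calibration for cheaper end-to-end checks."""
    schedule = build_schedule(3, SMALL_SCHEDULE)
    return simulate_calibration(schedule, SimulationParams(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
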
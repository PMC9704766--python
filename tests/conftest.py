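"""Shared fixtures: schedules, regulator parameter sets, synthetic tables.

All fixtures are generated programmatically and deterministically; the
heavier synthetic-experiment tables are session-scoped.
"""

import numpy as np
import pytest

from latstep import StepGoal
from latstep.dataio import default_lane_change_schedule, generate_synthetic_experiment
from latstep.maneuver import steady_schedule
from latstep.regulator import RegulatorParams


@pytest.fixture(scope="session")
def lane_schedule():
    """Default four-step lane change: z_B* -0.3 -> +0.3 m, w* 0.12 m, eps 0.03 m."""
    return default_lane_change_schedule()


@pytest.fixture(scope="session")
def steady_sched():
    return steady_schedule(StepGoal(0.0, 0.12), rho=0.9)


@pytest.fixture(scope="session")
def noiseless_regs():
    """(position, width) regulators with all noise off, gamma/alpha = 0.1."""
    return (
        RegulatorParams(q_star=0.0, gamma=0.1, sigma_a=0.0, sigma_m=0.0),
        RegulatorParams(q_star=0.12, gamma=0.1, sigma_a=0.0, sigma_m=0.0),
    )


@pytest.fixture(scope="session")
def accurate_regs():
    """Noisy but fully error-correcting regulators (gamma = 0, k ~= 1)."""
    return (
        RegulatorParams(q_star=0.0, gamma=0.0, sigma_a=0.01, sigma_m=0.001),
        RegulatorParams(q_star=0.12, gamma=0.0, sigma_a=0.02, sigma_m=0.002),
    )


@pytest.fixture(scope="session")
def synthetic_table():
    """Default synthetic experiment: 20 participants x 4 maneuvers."""
    return generate_synthetic_experiment(seed=101)


@pytest.fixture(scope="session")
def accurate_table(accurate_regs):
    """Synthetic experiment from goal-tracking regulators (k ~= 1).

    Used for parameter-recovery tests of the experimental-style
    estimators, which assume placements realize their goals on average.
    """
    reg_zB, reg_w = accurate_regs
    return generate_synthetic_experiment(seed=202, reg_zB=reg_zB, reg_w=reg_w)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
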
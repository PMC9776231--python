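"""Shared fixtures: synthetic structures reused across test modules.

Session scope keeps the optimizer-built sheet fixtures (a few seconds each)
from being rebuilt per test.
"""

import numpy as np
import pytest

from mdinteract import (
    Trajectory,
    make_dimer_trajectory,
    make_ideal_helix,
    make_ideal_sheet,
)
from mdinteract.synthetic import ScheduledContact


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def sheet_antiparallel():
    return make_ideal_sheet(8, "antiparallel")


@pytest.fixture(scope="session")
def sheet_parallel():
    return make_ideal_sheet(8, "parallel")


@pytest.fixture(scope="session")
def scheduled_dimer():
    """100-frame dimer: pairs at 85%, 0% and 100% scheduled occupancy."""
    schedule = [
        ScheduledContact(5, 5, 85.0),
        ScheduledContact(10, 10, 0.0),
        ScheduledContact(20, 20, 100.0),
    ]
    return make_dimer_trajectory(schedule, n_frames=100, noise_sd=0.0, seed=42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
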
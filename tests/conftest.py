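import numpy as np
import pytest

from csdsphys.arenas import epm_arena, oft_arena, si_arena
from csdsphys.cohort import CohortConfig
from csdsphys.core import Trajectory
from csdsphys.ephys_sim import MembraneParams


@pytest.fixture(scope="session")
def epm():
    return epm_arena()


@pytest.fixture(scope="session")
def oft():
    return oft_arena()


@pytest.fixture(scope="session")
def si():
    return si_arena()


@pytest.fixture
def membrane():
    return MembraneParams()


@pytest.fixture
def passive_membrane():
    """No Ih: a plain leaky integrate-and-fire cell."""
    return MembraneParams(g_h_nS=0.0)


@pytest.fixture
def small_cohort_cfg():
    return CohortConfig(n_ctl=6, n_stressed=12, seed=123)


def make_trajectory(arena, xs, ys, hz=30.0):
    """Trajectory from explicit sample positions (test scaffolding)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    t = np.arange(len(xs)) / hz
    return Trajectory(time_s=t, x_cm=xs, y_cm=ys, arena=arena)


@pytest.fixture
def traj_builder():
    return make_trajectory
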
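import numpy as np
import pytest

from conflictval.cohort import DEFAULT_SCHEDULE_SEED
from conflictval.rl import GridSpec, RLParams
from conflictval.task_design import generate_schedule


@pytest.fixture(scope="session")
def frozen_schedule():
    return generate_schedule(DEFAULT_SCHEDULE_SEED)


@pytest.fixture(scope="session")
def phase1(frozen_schedule):
    return frozen_schedule.phase(1)


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec.coarse()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def mid_params():
    return RLParams(
        alpha_chair=0.2,
        alpha_plane=0.3,
        beta_chair=3.0,
        beta_plane=3.0,
        v0_chair=0.5,
        v0_plane=0.5,
    )
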
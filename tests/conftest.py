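import numpy as np
import pytest

from otterpomdp import (
    Action,
    CutreeConfig,
    Discretization,
    ObservationParams,
    PopulationParams,
    RewardParams,
)


@pytest.fixture
def params():
    return PopulationParams()


@pytest.fixture
def rp():
    return RewardParams()


@pytest.fixture
def det_params():
    """Deterministic dynamics: no environmental noise, no spills."""
    return PopulationParams(sigma=0.0, f=0.0)


def make_band_disc():
    """Hand-built 3-state model (below band / band / above band) whose
    Bellman-optimal policy is [INTRODUCE, REDUCE_DAMAGE, DO_NOTHING] —
    the structure of the otter problem at a glance."""
    from otterpomdp import bellman_solve

    disc = Discretization(edges=np.array([0.0, 497.0, 746.0, 1000.0]), gamma=0.95)
    L, A = 3, 4
    T = np.zeros((L, A, L))
    # below band: stuck unless INTRODUCE, which usually reaches the band
    T[0, :, 0] = 1.0
    T[0, 3] = [0.1, 0.9, 0.0]
    # band: spills may eject; REDUCE_DAMAGE retains best, INTRODUCE risks
    # overshooting above the band
    T[1, 0] = [0.4, 0.6, 0.0]
    T[1, 1] = [0.3, 0.7, 0.0]
    T[1, 2] = [0.05, 0.95, 0.0]
    T[1, 3] = [0.1, 0.6, 0.3]
    # above band: drifts back toward the band regardless of action
    T[2, :] = [0.0, 0.8, 0.2]
    disc.T = T
    disc.R = np.array(
        [
            [0.0, -10.0, -10.0, -10.0],
            [100.0, 90.0, 90.0, 90.0],
            [0.0, -10.0, -10.0, -10.0],
        ]
    )
    disc.N = np.ones((L, A))
    bellman_solve(disc, tol=1e-12)
    assert list(disc.policy) == [
        int(Action.INTRODUCE),
        int(Action.REDUCE_DAMAGE),
        int(Action.DO_NOTHING),
    ]
    return disc


@pytest.fixture
def band_disc():
    return make_band_disc()
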
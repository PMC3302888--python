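import numpy as np
import pytest

from pibquant.kinetics import FrameSchedule
from pibquant.synthetic_data import (
    PlasmaInputParams,
    SRTMParams,
    make_frame_schedule,
    simulate_tac_pair,
)


@pytest.fixture(scope="session")
def schedule_52f() -> FrameSchedule:
    return make_frame_schedule("52f")


@pytest.fixture(scope="session")
def plasma() -> PlasmaInputParams:
    return PlasmaInputParams()


@pytest.fixture(scope="session")
def slow_plasma() -> PlasmaInputParams:
    """Input with a very slow terminal tail; late frames sit in transient
    equilibrium, where ratio estimators approach DVR."""
    return PlasmaInputParams(clearance_per_min=0.002)


@pytest.fixture(scope="session")
def noiseless_pair(plasma, schedule_52f):
    """Reference and target TACs for consistent kinetics at BP_ND = 0.5."""
    params = SRTMParams.consistent(bp_nd=0.5)
    ref, tgt = simulate_tac_pair(plasma, params, schedule_52f)
    return ref, tgt, params


@pytest.fixture(scope="session")
def blob_volume() -> np.ndarray:
    """Smooth multi-blob phantom volume used by the registration tests."""
    rng = np.random.default_rng(7)
    shape = (48, 48, 48)
    vol = np.zeros(shape)
    grid = np.indices(shape).astype(float)
    for _ in range(6):
        c = rng.uniform(12, 36, 3)
        s = rng.uniform(3, 7)
        vol += rng.uniform(0.5, 1.5) * np.exp(
            -((grid[0] - c[0]) ** 2 + (grid[1] - c[1]) ** 2 + (grid[2] - c[2]) ** 2) / (2 * s * s)
        )
    return vol
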
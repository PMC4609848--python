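import numpy as np
import pytest

from pdcest import defaults
from pdcest.bloch import PoolParams, SaturationParams
from pdcest.schedule import OffsetSchedule


@pytest.fixture(scope="session")
def sat() -> SaturationParams:
    return defaults.DEFAULT_SATURATION


@pytest.fixture(scope="session")
def schedule() -> OffsetSchedule:
    return OffsetSchedule.default()


@pytest.fixture(scope="session")
def sorted_offsets(schedule) -> np.ndarray:
    return np.array(sorted(schedule.offsets))


@pytest.fixture(scope="session")
def water_pool() -> PoolParams:
    return defaults.WATER_POOL


@pytest.fixture(scope="session")
def two_pool(water_pool) -> list[PoolParams]:
    """Water + amide, the minimal asymmetric system."""
    return [water_pool, PoolParams("amide", 2e-3, 3.5, 30.0, t1=1.0, t2=0.03)]


@pytest.fixture(scope="session")
def four_pool() -> list[PoolParams]:
    return defaults.make_pools(3.9e-3)
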
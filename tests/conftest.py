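import numpy as np
import pytest

from scspace import indicators as ind
from scspace import synthetic as syn
from scspace import triangle as tri


@pytest.fixture(scope="session")
def small_spec():
    return syn.ScenarioSpec(nlat=36, nlon=72, seed=11, n_gcms=4)


@pytest.fixture(scope="session")
def climate(small_spec):
    return syn.generate_climate(small_spec)


@pytest.fixture(scope="session")
def baseline(climate):
    return climate[0]


@pytest.fixture(scope="session")
def futures(climate):
    return climate[1]


@pytest.fixture(scope="session")
def indicators_baseline(baseline):
    return ind.indicators_from_climate(baseline)


@pytest.fixture(scope="session")
def triangle_baseline(indicators_baseline):
    return tri.to_triangle(
        np.asarray(indicators_baseline["P"]),
        np.asarray(indicators_baseline["pet_ratio"]),
    )


@pytest.fixture(scope="session")
def production(indicators_baseline):
    return syn.generate_production(11, indicators_baseline)


@pytest.fixture(scope="session")
def zone_table():
    return tri.ZoneTable.default()
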
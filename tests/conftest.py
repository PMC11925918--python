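import numpy as np
import pytest

import heatrisk as hr


@pytest.fixture(scope="session")
def small_scenario() -> hr.SyntheticScenario:
    """64 x 64 scenario, fast enough for per-test use."""
    return hr.SyntheticScenario(shape=(64, 64), seed=7)


@pytest.fixture(scope="session")
def small_region(small_scenario):
    return hr.make_study_region(small_scenario)


@pytest.fixture(scope="session")
def small_stack(small_scenario, small_region):
    stack, truth = hr.gen_indicator_stack(small_scenario, small_region, 2010)
    return stack, truth


def grid_from(values, mask=None, **kw) -> hr.Grid:
    values = np.asarray(values, dtype=float)
    return hr.Grid(values, mask, **kw)
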
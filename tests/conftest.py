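import numpy as np
import pytest

from adchist import RunConfig, cohort_metrics
from adchist.adcfit import compute_adc_map
from adchist.phantom import PhantomConfig, build_phantom_case, case_seed_for

SMALL_GRID = (48, 48, 14)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=SMALL_GRID, seed=7)


@pytest.fixture(scope="session")
def small_case(small_config):
    return build_phantom_case(small_config, case_seed_for(7, "001"), "001")


@pytest.fixture(scope="session")
def small_case_adc(small_case):
    return compute_adc_map(small_case.dwi)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-case cohort on a reduced grid: (metrics frame, labels frame)."""
    cfg = RunConfig(master_seed=11, n_cases=8)
    cfg.phantom.grid_shape = SMALL_GRID
    return cohort_metrics(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
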
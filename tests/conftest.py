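import numpy as np
import pytest

from gcmm import AnalysisConfig, default_catalog, filter_last_year_gamblers
from gcmm.simulate import GeneratorParams, generate_survey

SEED = 1234


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey (three years, ~1500 respondents) with truth."""
    params = GeneratorParams(n_per_year=(500, 500, 500), rng_seed=SEED)
    return generate_survey(params)


@pytest.fixture(scope="session")
def gamblers(small_survey):
    table, _ = small_survey
    return filter_last_year_gamblers(table)


@pytest.fixture(scope="session")
def fast_config():
    """Low-B configuration for pipeline-level tests."""
    return AnalysisConfig(bootstrap_B=200, rng_seed=SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
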
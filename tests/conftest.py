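import numpy as np
import pytest

from ippwlab.datagen import GenerativeParams, generate_cohort, get_scenario


@pytest.fixture(scope="session")
def big_cohort():
    """One large MAR 1 cohort for moment checks (n = 200,000)."""
    params = GenerativeParams(n=200_000)
    scenario = get_scenario("MAR 1", params)
    return generate_cohort(scenario, params, seed=42)


@pytest.fixture()
def small_cohort():
    """A small cohort for fast estimator tests."""
    params = GenerativeParams(n=400)
    scenario = get_scenario("MNAR 2", params)
    return generate_cohort(scenario, params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
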
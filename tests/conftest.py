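import pytest

from ssbtax.config import SyntheticConfig, TaxScenario
from ssbtax.pipeline import run_scenario
from ssbtax.synthetic import generate_inputs


@pytest.fixture(scope="session")
def bundle():
    """Full 29-disease bundle at the default study conditions."""
    return generate_inputs(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced 4-disease bundle for tests that re-run the pipeline many times."""
    return generate_inputs(SyntheticConfig(seed=2, n_diseases=4))


@pytest.fixture(scope="session")
def base_scenario():
    return TaxScenario()


@pytest.fixture(scope="session")
def base_result(bundle, base_scenario):
    """One shared base-case run of the full bundle."""
    return run_scenario(bundle, base_scenario)


@pytest.fixture(scope="session")
def small_result(small_bundle, base_scenario):
    return run_scenario(small_bundle, base_scenario)
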
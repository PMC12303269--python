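import pytest

from drainspec.pipeline import prepare_snv
from drainspec.simulate import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact patient-structured cohort shared across tests."""
    config = SyntheticConfig(n_patients=40, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def snv_data(small_cohort):
    cubes, panels, _truth = small_cohort
    return prepare_snv(cubes, panels)
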
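import numpy as np
import pytest

from agfn.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient cohort shared by the cheap pipeline-level tests."""
    return simulate_cohort(SimConfig(n_patients=120, seed=5))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort (n=2000); generated once per session."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
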
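import numpy as np
import pytest

from psycohort.synthetic_cohort import GeneratorConfig, generate_cohort, preset


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort shared by cheap structural tests."""
    return generate_cohort(GeneratorConfig(n_f3=40, n_f2=30, seed=11))


@pytest.fixture(scope="session")
def paper_f2_cohort():
    return generate_cohort(preset("paper-f2", seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
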
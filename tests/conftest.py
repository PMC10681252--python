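import numpy as np
import pytest

from totonou import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_inear_cohort():
    """Two participants per group, rest recordings only (shared, read-only)."""
    return simulate_cohort(CohortDesign(n_per_group=2, seed=5),
                           modalities=("inear",))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
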
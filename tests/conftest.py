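import numpy as np
import pytest

from pneumocl.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-image rendered cohort shared across tests (seeded)."""
    spec = CohortSpec(n=300, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def meta_cohort():
    """A metadata-only 2000-sample cohort (no pixels; fast)."""
    spec = CohortSpec(n=2000, seed=7, render=False)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
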
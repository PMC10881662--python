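import pytest

from dyadgrid import TaskConfig
from dyadgrid.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """9-dyad cohort (3 per planted type) shared across tests."""
    spec = CohortSpec(
        n_per_type={"both_low": 3, "both_high": 3, "mixed": 3}, seed=42
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 28-dyad default cohort at a fixed seed."""
    return generate_cohort(CohortSpec(seed=1))
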
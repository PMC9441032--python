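import pytest
from hypothesis import settings

from optimise_smi import CohortConfig, generate_cohort, load_knowledge_base

settings.register_profile("derandomised", derandomize=True, deadline=None)
settings.load_profile("derandomised")


@pytest.fixture(scope="session")
def kb():
    """The packaged 62-indicator knowledge base."""
    return load_knowledge_base()


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged-seed 20-patient synthetic cohort."""
    return generate_cohort(CohortConfig())
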
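import pytest

from smoltsort import default_paper_config, generate_cohort


@pytest.fixture(scope="session")
def small_labeled():
    """A small labelled synthetic cohort shared across tests (400/treatment)."""
    return generate_cohort(default_paper_config(n_per_treatment=400, seed=11))


@pytest.fixture(scope="session")
def default_labeled():
    """A default-scale labelled cohort (1500/treatment) for recovery tests."""
    return generate_cohort(default_paper_config(n_per_treatment=1500, seed=23))
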
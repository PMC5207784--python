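import pytest

from pgxpanel import load_panel
from pgxpanel.simulate import cohort_from_counts, load_cohort_counts


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def counts():
    return load_cohort_counts()


@pytest.fixture(scope="session")
def cohort():
    """Marginal cohort reconstructed from the built-in 506-subject
    diplotype counts."""
    return cohort_from_counts()
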
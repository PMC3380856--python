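import pytest

from genecult.synthetic_data import fixtures


@pytest.fixture(scope="session")
def study():
    """Packaged study tables (genotype counts and pollen dates)."""
    return fixtures()


@pytest.fixture(scope="session")
def table1(study):
    return study.table1


@pytest.fixture(scope="session")
def table2(study):
    return study.table2
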
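import pytest

from iemscreen import CutoffTable, load_genotypes, load_patterns, load_published_counts


@pytest.fixture(scope="session")
def cutoffs():
    return CutoffTable.load()


@pytest.fixture(scope="session")
def schema(cutoffs):
    return cutoffs.schema()


@pytest.fixture(scope="session")
def patterns():
    return load_patterns()


@pytest.fixture(scope="session")
def genotypes():
    return load_genotypes()


@pytest.fixture(scope="session")
def published_counts():
    return load_published_counts()
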
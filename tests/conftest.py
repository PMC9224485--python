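import pytest

from nanoperm import datasets


@pytest.fixture(scope="session")
def filters():
    """The packaged mesh-filter library keyed by label."""
    return datasets.load_filters()


@pytest.fixture(scope="session")
def retention_table():
    """The measured retention table (one row per configuration x particle)."""
    return datasets.load_retention_table()


@pytest.fixture(scope="session")
def nano_ag():
    return datasets.nano_silver()


@pytest.fixture(scope="session")
def nano_cu():
    return datasets.nano_copper()


@pytest.fixture(scope="session")
def water():
    return datasets.water()


@pytest.fixture(scope="session")
def franz_conditions():
    return datasets.franz_cell_conditions()
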
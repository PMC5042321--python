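import pytest

from syntherm import Conditions, default_table, make_paper_fixture


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture()
def standard():
    return Conditions.standard()


@pytest.fixture()
def physiological():
    return Conditions.physiological()


@pytest.fixture(scope="session")
def paper_fixture():
    """The frozen 10-clone / 57-variant panel with its phenotype labels."""
    return make_paper_fixture()
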
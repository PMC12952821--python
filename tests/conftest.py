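import pytest

from aromatrace import fixtures
from aromatrace.types import Stage


@pytest.fixture(scope="session")
def synonyms():
    return fixtures.load_synonyms()


@pytest.fixture(scope="session")
def leaf_table(synonyms):
    return fixtures.load_stage_table(Stage.LEAF, synonyms)


@pytest.fixture(scope="session")
def py_table(synonyms):
    return fixtures.load_stage_table(Stage.PYROLYSIS, synonyms)


@pytest.fixture(scope="session")
def smoke_table(synonyms):
    return fixtures.load_stage_table(Stage.SMOKE, synonyms)


@pytest.fixture(scope="session")
def transfer_averages():
    return fixtures.load_transfer_averages()


@pytest.fixture(scope="session")
def notes_labels():
    return fixtures.load_notes_labels()
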
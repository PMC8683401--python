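import pytest

from famscreen import fixtures as fx


@pytest.fixture(scope="session")
def table1():
    """All 30 packaged candidate records (29 members + truncated rejection)."""
    return fx.load_table1()


@pytest.fixture(scope="session")
def members(table1):
    """The 29 accepted family members (records with coordinates)."""
    return [r for r in table1 if r.chromosome is not None]


@pytest.fixture(scope="session")
def table3():
    return fx.load_table3()


@pytest.fixture(scope="session")
def consensus_key():
    return fx.load_consensus_key()
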
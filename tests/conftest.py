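import pytest

from evcolor import calling, fixtures, panel


@pytest.fixture(scope="session")
def default_panel():
    return panel.load_panel()


@pytest.fixture(scope="session")
def table1(default_panel):
    return fixtures.load_fixture_table1(default_panel)


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_fixture_table2()


@pytest.fixture(scope="session")
def guide():
    """(decision table, accuracy lookup, darkness orders)."""
    return calling.load_calling_config()


@pytest.fixture(scope="session")
def consensus_by_sample(default_panel, table1):
    return {
        row.profile.sample_id: panel.consensus_merge([row.profile], default_panel)
        for row in table1
    }
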
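import pytest

from fpnhse.paperdata import load_paper_fixture


@pytest.fixture(scope="session")
def fixture():
    """The packaged worked-example tables (as printed)."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def errata_cells(fixture):
    """Set of (table, row, col) keys of documented printed-table slips."""
    return {(e.table, e.row, e.col) for e in fixture.errata}
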
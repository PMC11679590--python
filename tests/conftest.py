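import pytest

from amplityper import fixtures as fx


@pytest.fixture(scope="session")
def paper_panel():
    """The synthetic five-species barcode panel, one row per species."""
    return fx.make_paper_panel(seed=11)


@pytest.fixture(scope="session")
def paper_alignment(paper_panel):
    return paper_panel.alignment()


@pytest.fixture(scope="session")
def primers():
    return fx.paper_primers()


@pytest.fixture(scope="session")
def assay(paper_panel):
    return fx.paper_assay(diagnostic_columns={
        sp: tuple(cols) for sp, cols in paper_panel.diagnostic_columns.items()})
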
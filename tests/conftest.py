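import pytest

from donorsense import io


@pytest.fixture(scope="session")
def table4():
    """The packaged 31-day campaign delivery table."""
    return io.load_table4()


@pytest.fixture(scope="session")
def gazetteer():
    return io.load_demo_gazetteer()
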
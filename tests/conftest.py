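import pytest

from litgraph.fixtures import worked_example_fixture


@pytest.fixture(scope="session")
def wex():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def wex_result(wex):
    """The worked-example corpus pushed through the full pipeline once."""
    return wex.run()
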
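import pytest

from tkicea import ModelSettings, evaluate_strategies, table2_fixture


@pytest.fixture(scope="session")
def book():
    return table2_fixture()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_results(book, settings):
    """Base-case cost/LY/QALY table for the four strategies (reused widely)."""
    return evaluate_strategies(book, settings)
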
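import pytest

from compartnet.synthetic import (
    GeneratorConfig,
    single_gap_fixture,
    generate,
    worked_example_evidence,
    worked_example_fixtures,
)


@pytest.fixture
def single_gap():
    return single_gap_fixture()


@pytest.fixture
def worked():
    return worked_example_fixtures()


@pytest.fixture
def worked_evidence():
    return worked_example_evidence()


@pytest.fixture(scope="session")
def default_data():
    """One generated study set shared by read-only tests."""
    return generate(GeneratorConfig(seed=11))
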
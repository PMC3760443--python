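import pytest

from acylforms import EnumConfig, enumerate_forms, flounder_context


@pytest.fixture(scope="session")
def context():
    return flounder_context()


@pytest.fixture(scope="session")
def candidates(context):
    """Default candidate space on the flounder ghrelin context."""
    return enumerate_forms(context, EnumConfig())
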
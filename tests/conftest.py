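import pytest

from tiletopo.knots import KnotEngine


@pytest.fixture(scope="session")
def engine() -> KnotEngine:
    """One engine per session: templates and catalog are loaded once and
    the basic-sealing lookups are shared across tests."""
    return KnotEngine()
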
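import pytest

from vetamc.reference import reference_tables
from vetamc.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reference():
    return reference_tables()
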
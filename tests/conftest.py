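import pytest

from stricture_econ import default_parameters


@pytest.fixture(scope="session")
def params():
    """Packaged default configuration (session-scoped, treated as read-only;
    tests that mutate must copy)."""
    return default_parameters()
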
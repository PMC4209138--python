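import pytest

from orthoprune.simulate import SimConfig, emit_fixture_set


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One small simulated dataset shared by the I/O and CLI tests."""
    out = tmp_path_factory.mktemp("fixtures")
    emit_fixture_set(SimConfig(n_families=6, seed=2024), out)
    return out
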
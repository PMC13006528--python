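import pytest

from tagsite.synthetic import FixtureSpec, make_fixture_protein


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One deterministic synthetic input bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture_protein(FixtureSpec(length=100, seed=7), out)
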
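import pytest

from lophopax import domains, motifs


@pytest.fixture(scope="session")
def profiles():
    return domains.default_profiles()


@pytest.fixture(scope="session")
def registry():
    return motifs.load_motif_registry()
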
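import pytest

from ttckit.cramer import load_lookup_lists, load_tree
from ttckit.curation import load_exclusion_rules


@pytest.fixture(scope="session")
def tree():
    return load_tree()


@pytest.fixture(scope="session")
def lists():
    return load_lookup_lists()


@pytest.fixture(scope="session")
def rules():
    return load_exclusion_rules()
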
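import pytest

from symbiophylo.taxonomy import toy_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    """Bundled 14-category test taxonomy: (tree, category_map)."""
    return toy_taxonomy()


@pytest.fixture(scope="session")
def tax_tree(taxonomy):
    return taxonomy[0]


@pytest.fixture(scope="session")
def category_map(taxonomy):
    return taxonomy[1]
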
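import pytest

from ratechange_miner import resources


@pytest.fixture(scope="session")
def rate_ontology():
    return resources.rate_change_ontology()


@pytest.fixture(scope="session")
def negative_ontology():
    return resources.negative_ontology()


@pytest.fixture(scope="session")
def regulate_lexicon():
    return resources.regulate_lexicon()


@pytest.fixture(scope="session")
def rate_change_lexicon():
    return resources.rate_change_lexicon()


@pytest.fixture(scope="session")
def gene_dictionary():
    return resources.gene_dictionary()


@pytest.fixture(scope="session")
def norm_dictionary():
    return resources.normalization_dictionary()


@pytest.fixture(scope="session")
def fixture_sentences():
    from ratechange_miner.synthetic_corpus import fixtures

    return fixtures()


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 300-sentence synthetic corpus shared across tests."""
    from ratechange_miner.synthetic_corpus import GeneratorConfig, generate

    return generate(GeneratorConfig(n_sentences=300, seed=11))
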
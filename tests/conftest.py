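import pytest

from spicemine.synthetic import (
    SyntheticConfig,
    generate_corpus,
    generate_lexicon,
    generate_ontology,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        seed=11,
        n_categories=6,
        subcats_per_category=(2, 4),
        diseases_per_subcat=(2, 4),
        n_spices=8,
        n_abstracts=60,
        sentences_per_abstract=(2, 5),
    )


@pytest.fixture(scope="session")
def small_ontology(small_cfg):
    return generate_ontology(small_cfg)


@pytest.fixture(scope="session")
def small_lexicon(small_cfg):
    return generate_lexicon(small_cfg)


@pytest.fixture(scope="session")
def small_corpus(small_cfg, small_ontology, small_lexicon):
    return generate_corpus(small_cfg, small_ontology, small_lexicon)
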
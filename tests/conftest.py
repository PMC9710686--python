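import pytest

from bioground.disambiguation import DisambRegistry, train_model
from bioground.fixtures import (
    SyntheticCorpusSpec,
    dap4_fixture,
    generate_ambiguous_corpus,
    pkc_fixture,
)
from bioground.lexicon import build_index
from bioground.stringmatch import Grounder

#: sense labels used for the DAP4 ambiguity fixture, sorted as the
#: classifier will sort them
DAP4_SENSES = [("HGNC", "16958"), ("HGNC", "24476")]


@pytest.fixture(scope="session")
def pkc_index():
    return build_index(pkc_fixture())


@pytest.fixture(scope="session")
def dap4_index():
    return build_index(dap4_fixture())


@pytest.fixture(scope="session")
def dap4_corpus():
    spec = SyntheticCorpusSpec(
        n_senses=2, docs_per_sense=100, vocab_size_per_sense=50,
        shared_vocab_fraction=0.0, doc_length=40, seed=7, entity_text="DAP4",
    )
    return generate_ambiguous_corpus(spec, senses=DAP4_SENSES)


@pytest.fixture(scope="session")
def dap4_model(dap4_corpus):
    return train_model(dap4_corpus, seed=7)


@pytest.fixture(scope="session")
def dap4_grounder(dap4_index, dap4_model):
    return Grounder(index=dap4_index, models=DisambRegistry([dap4_model]))
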
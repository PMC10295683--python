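import numpy as np
import pytest

from ohcner.corpus_io import spans_to_bio
from ohcner.synthetic import GeneratorConfig, generate_corpus
from ohcner.vocab import Vocab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic consultation documents with bookkeeping."""
    docs, books = generate_corpus(GeneratorConfig(n_documents=60, seed=7))
    return docs, books


@pytest.fixture(scope="session")
def small_slices(small_corpus):
    docs, _ = small_corpus
    return [spans_to_bio(d) for d in docs]


@pytest.fixture(scope="session")
def small_vocab(small_slices):
    return Vocab.build(s.text for s in small_slices)
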
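import numpy as np
import pytest

from dialectnet import (
    GenSpec, build_aae_corpus, generate_lexicon, load_toy_dialect_corpus,
    load_toy_lexicon,
)
from dialectnet.lexicon import PhonemeInventory
from dialectnet.network import NetConfig, init_network


@pytest.fixture(scope="session")
def inventory():
    return PhonemeInventory()


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_toy_lexicon()


@pytest.fixture(scope="session")
def toy_corpus():
    return load_toy_dialect_corpus(seed=0)


@pytest.fixture(scope="session")
def synth_lexicon_50():
    return generate_lexicon(GenSpec(n_words=50, seed=11))


@pytest.fixture(scope="session")
def synth_corpus_50(synth_lexicon_50):
    return build_aae_corpus(synth_lexicon_50, seed=11)


@pytest.fixture
def tiny_config():
    """A few-unit network, large enough to exercise every weight block."""
    return NetConfig(
        n_orth=4, n_hidden=3, n_phon=5, n_cleanup=2, n_context=2,
        settle_steps=6, clamp_steps=2, target_steps=2,
        learning_rate=0.01, seed=1,
    )


@pytest.fixture
def tiny_net(tiny_config):
    return init_network(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
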
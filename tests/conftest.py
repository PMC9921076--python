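import numpy as np
import pytest

import rxnyield as ry


@pytest.fixture(scope="session")
def small_corpus():
    """A 300-reaction synthetic corpus shared across tests."""
    return ry.generate_corpus(ry.SimulationConfig(n_reactions=300, seed=42))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return ry.build_vocabulary(small_corpus)


@pytest.fixture(scope="session")
def schema():
    return ry.EquivalentSchema()


@pytest.fixture(scope="session")
def tiny_config(small_vocab):
    return ry.ModelConfig(
        vocab_size=len(small_vocab),
        max_sequence_length=96,
        hidden_size=16,
        attention_heads=2,
        layers=1,
        dropout=0.0,
        learning_rate=2e-3,
        batch_size=32,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
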
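import numpy as np
import pytest

from lncstage.synthetic_data import generate_sequences, preset_config


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded transcript corpus shared across tests (60+60 records)."""
    config = preset_config("small", seed=5)
    records, truth = generate_sequences(config)
    return config, records, truth


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    from lncstage.coding_potential import train_model_from_corpus

    _, records, truth = small_corpus
    coding = [r for r in records if truth.classes[r.transcript_id] == "coding"]
    noncoding = [r for r in records if truth.classes[r.transcript_id] == "noncoding"]
    return train_model_from_corpus(coding, noncoding)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
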
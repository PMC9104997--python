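import numpy as np
import pytest

from iltox.chem import featurize_records
from iltox.embedding import EmbeddingModel, train_fixture_embedding
from iltox.synthetic import SyntheticSpec, generate_corpus, generate_toxicity_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 synthetic IL records with known ground truth (seed 5)."""
    records, truth = generate_toxicity_dataset(
        SyntheticSpec(n_records=40, noise_sd=0.2, seed=5))
    return records, truth


@pytest.fixture(scope="session")
def zero_embedding():
    return EmbeddingModel.zeros(300)


@pytest.fixture(scope="session")
def tiny_embedding():
    """Fixture skip-gram model trained on a 60-sentence template corpus."""
    return train_fixture_embedding(generate_corpus(60, seed=9), dim=300,
                                   seed=9, epochs=2)


@pytest.fixture(scope="session")
def small_features(small_dataset, zero_embedding):
    """Feature matrix and labels for the 40-record fixture (zero embedding,
    so all signal sits in the descriptor block, as in the true law)."""
    records, _ = small_dataset
    x = featurize_records(records, zero_embedding)
    y = np.array([r.label for r in records])
    return x, y
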
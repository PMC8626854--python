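import numpy as np
import pytest

from glossbench import cnn_zoo as cz
from glossbench import observer_sim as osim
from glossbench import stimulus_synth as ss


@pytest.fixture(scope="session")
def small_manifest():
    """30-scene corpus at 32 px with a 20% validation split."""
    m = ss.build_corpus(30, seed=11, size=32)
    return ss.split_corpus(m, set(), 0.2, seed=3)


@pytest.fixture(scope="session")
def train_data(small_manifest):
    return cz.train_data_from_split(small_manifest, size=32)


@pytest.fixture(scope="session")
def trained_cnn(train_data):
    """One 3-layer network trained to convergence on the small corpus."""
    spec = cz.build_architecture(3, [8, 8, 8], [3, 3, 3], input_size=32)
    hp = cz.TrainingHyperParams(
        learning_rate=0.01, momentum=0.9, l2=1e-4, val_interval=50, patience=5, max_steps=800, init_seed=0
    )
    return cz.train_with_early_stopping(spec, hp, train_data)


@pytest.fixture(scope="session")
def corpus_evidence(small_manifest):
    """Latent gloss evidence per corpus image (64 px, the calibrated size)."""
    return osim.evidence_for_manifest(small_manifest, size=64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
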
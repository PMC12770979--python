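import numpy as np
import pytest

import motifattn as ma


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_library():
    return ma.random_library(4, np.random.default_rng(11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """400 sequences, 2 motifs, 1 implanted pair (simulator unit tests)."""
    lib = ma.random_library(2, np.random.default_rng(3))
    cfg = ma.SimulationConfig(n_sequences=400, seq_length=120, n_motifs=2,
                              n_pairs=1, pairs_per_positive=(1, 1), seed=5)
    ds, truth = ma.generate_dataset(cfg, lib)
    return ds, truth, lib, cfg


@pytest.fixture(scope="session")
def tiny_trained():
    """A model trained on a small 6-motif / 3-pair dataset, large enough for
    interaction inference to find support (shared across tests)."""
    lib = ma.random_library(6, np.random.default_rng(3))
    cfg = ma.SimulationConfig(n_sequences=3000, seq_length=200, n_motifs=6,
                              n_pairs=3, pairs_per_positive=(2, 3), seed=5)
    ds, truth = ma.generate_dataset(cfg, lib)
    splits = ma.split_dataset(ds, rng=0)
    spec = ma.ModelSpec(entropy_lambda=1e-2)
    tcfg = ma.TrainConfig(epochs=4, seeds=(0,))
    result = ma.train_model(spec, tcfg, splits)
    return result, splits, truth, lib
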
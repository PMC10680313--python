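import dataclasses

import numpy as np
import pytest

from synmtl import io, pipeline
from synmtl.config import Config
from synmtl.synthetic import SyntheticConfig, generate_dataset

TINY = SyntheticConfig(n_drugs=12, n_cells=6, n_genes=300, k_genes=150,
                       pair_fraction=0.8, seed=3)

TINY_CFG = Config(seed=3, k_genes=150, c_drug=32, c_cell=32,
                  ae_epochs=40, ae_patience=10,
                  shared_first_layer=64, max_epochs=10, patience=5,
                  batch_size=64, learning_rate=1e-3)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic screen: 12 drugs x 6 cell lines, planted signal."""
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def tiny_samples(tiny_dataset):
    return io.synergy_samples_from_frame(tiny_dataset.synergy)


@pytest.fixture(scope="session")
def tiny_sensitivity(tiny_dataset):
    return io.sensitivity_samples_from_frame(tiny_dataset.sensitivity)


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset, tiny_samples, tiny_sensitivity):
    """Fully prepared pipeline state (features, encoders, encoded data)."""
    ds = tiny_dataset
    # copies: fold assignment mutates samples, and other tests reuse them
    samples = [dataclasses.replace(s) for s in tiny_samples]
    sensitivity = {k: dataclasses.replace(v) for k, v in tiny_sensitivity.items()}
    return pipeline.prepare_from_tables(
        ds.drugs, np.log2(ds.expression + 1.0), ds.annotations,
        samples, sensitivity, TINY_CFG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
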
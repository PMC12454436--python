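"""Shared fixtures: small synthetic datasets and a trained decoder.

Everything is generated at test time from the package's own simulator;
heavy objects are session-scoped so training happens once.
"""

import numpy as np
import pytest

import fingerdec as fd
from fingerdec import decoder as dec, preprocess as pre


N_CHANNELS = 48          # reduced sensor count for test speed


@pytest.fixture(scope="session")
def forward_model():
    return fd.build_forward_model(n_channels=N_CHANNELS, seed=1)


@pytest.fixture(scope="session")
def small_dataset(forward_model):
    """360-trial high-SNR dataset (6 blocks x 5 cycles), z-scored correct trials."""
    cfg = fd.SRTTConfig(cycles_per_block=5, n_blocks=6)
    table, epochs, truth = fd.simulate_subject(3, cfg=cfg, fm=forward_model)
    epochs = pre.select_correct(epochs, table)
    epochs = pre.zscore_epochs(epochs)
    return table, epochs, truth


@pytest.fixture(scope="session")
def test_hp():
    """Reduced-scale hyperparameters used throughout the test suite."""
    return dec.LFCNNHyperparams(k=8, p=7, max_epochs=60, patience=8,
                                batch_size=150)


@pytest.fixture(scope="session")
def trained_four(small_dataset, test_hp):
    """Nested-CV four-class training on the small high-SNR dataset."""
    _, epochs, _ = small_dataset
    return dec.train(epochs, task="four", hp=test_hp, seed=0)


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results do not depend
    # on which other tests ran before
    return np.random.default_rng(12345)
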
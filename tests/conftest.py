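"""Shared fixtures: small trained models used across the test modules.

Training is deliberately tiny (120 images, 32x32, 8x8 latents) so the
session-scoped fixtures build in well under a minute on one CPU.
"""

import numpy as np
import pytest

from iltm import synthetic as syn
from iltm import transformer as tr
from iltm import vqvae as vq


@pytest.fixture(scope="session")
def small_dataset():
    return syn.build_dataset(120, 0.5, seed=2024)


@pytest.fixture(scope="session")
def trained_vqvae(small_dataset):
    cfg = vq.VqvaeConfig(hidden=32, n_z=8, K=32, epochs=20, lr=2e-3,
                         revive_dead_codes=True)
    return vq.train_vqvae(small_dataset, cfg, seed=7)


@pytest.fixture(scope="session")
def token_sequences(trained_vqvae, small_dataset):
    grids = vq.tokens_for(trained_vqvae, small_dataset.images)
    return grids.reshape(len(grids), -1)


@pytest.fixture(scope="session")
def trained_prior(token_sequences):
    cfg = tr.TransformerConfig(vocab=32, context=65, d_model=48, n_heads=2,
                               n_layers=2, d_ff=96, epochs=12, lr=3e-3,
                               batch_size=64)
    return tr.train_transformer(token_sequences, None, cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
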
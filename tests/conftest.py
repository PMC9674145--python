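"""Shared fixtures: desk-scale datasets and smoke-trained models.

The heavy session fixtures (64 leaves at side 64, 30-epoch trainings)
are shared between the unit tests and the acceptance tests so each model
is trained exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from l2l.evaluate import AeConfig, AnomalyAutoencoder
from l2l.fixtures import LeafSpec, make_dataset
from l2l.pix2pix import GanConfig, Pix2Pix, TranslationPair
from l2l.preprocess import preprocess_sample
from l2l.resvae import ResidualVAE, VaeConfig

SIDE = 64
N_SMOKE = 64
SMOKE_EPOCHS = 30


@pytest.fixture(scope="session")
def leaf_dataset():
    return make_dataset(N_SMOKE, LeafSpec(side=SIDE), seed=0)


@pytest.fixture(scope="session")
def preprocessed(leaf_dataset):
    return [preprocess_sample(s.image, s.probes, side=SIDE) for s in leaf_dataset]


@pytest.fixture(scope="session")
def rgb_images(preprocessed):
    return [p.image.select(("R", "G", "B")) for p in preprocessed]


@pytest.fixture(scope="session")
def vae_smoke(preprocessed):
    cfg = VaeConfig(image_side=SIDE, epochs=SMOKE_EPOCHS, seed=0)
    return ResidualVAE([p.skeleton for p in preprocessed], cfg).fit()


@pytest.fixture(scope="session")
def gan_smoke(preprocessed):
    pairs = [TranslationPair(p.skeleton, p.image.select(("R", "G", "B")))
             for p in preprocessed]
    return Pix2Pix(pairs, GanConfig(image_side=SIDE, epochs=SMOKE_EPOCHS, seed=0)).fit()


@pytest.fixture(scope="session")
def ae_smoke(rgb_images):
    cfg = AeConfig(image_side=SIDE, epochs=SMOKE_EPOCHS, seed=0)
    return AnomalyAutoencoder(rgb_images, cfg).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_vae_config():
    """Fast configuration for determinism / contract tests."""
    return VaeConfig(latent_dim=8, image_side=16, base_channels=2,
                     n_residual_blocks=1, epochs=2, batch_size=4, seed=3)
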
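"""Shared fixtures.

The desk-scale enhancement study (200 training pairs, 15 epochs) is the
most expensive artifact any test needs, so it is built once per session
and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import octenhance as oe

DESK_SEED = 11


@pytest.fixture(scope="session")
def desk_dataset() -> oe.PhantomDataset:
    """250 phantoms at the default study conditions (64x64, gaussian
    sigma 0.1, 9-frame averaging): 200 train / 50 held-out."""
    return oe.make_paired_dataset(250, oe.DatasetConfig(), seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_model(desk_dataset) -> tuple[oe.EnhancementNetwork, list[float]]:
    """brunet94 (3 levels, 8 base channels) trained 15 epochs on the desk
    dataset; returns (network, loss history)."""
    net = oe.build_network(
        oe.NetworkSpec(family="brunet94", levels=3, base_channels=8), seed=5
    )
    cfg = oe.TrainConfig(epochs=15, learning_rate=1e-3, batch_size=8,
                         augmentation=None, seed=5)
    _, history = oe.train_network(net, desk_dataset.train, cfg)
    return net, history


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_truth() -> oe.PhantomTruth:
    return oe.generate_clean_bscan(oe.PhantomConfig(), seed=7)
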
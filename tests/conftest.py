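from __future__ import annotations

import numpy as np
import pytest

from pelletgran import CalibratedImage, PelletPopulation, render_binary_discs, render_pile


@pytest.fixture
def random_image():
    """Factory for seeded random 8-bit-valued images."""

    def make(seed: int, shape=(32, 32)) -> CalibratedImage:
        rng = np.random.default_rng(seed)
        return CalibratedImage(rng.integers(0, 256, size=shape).astype(float), 0.072)

    return make


@pytest.fixture(scope="session")
def disc_scene():
    """Three disjoint exact discs of radius 5 (the granulometry oracle fixture)."""
    img, truth = render_binary_discs(5, 3, (96, 128), seed=11)
    return img, truth


@pytest.fixture(scope="session")
def pellet_pile():
    """A small seeded pile of 1.1 mm-class pellets (lying only, sparse)."""
    pop = PelletPopulation(
        diameter_mean=1.236, diameter_sd=0.053, length_mean=1.85, length_sd=0.1,
        count=18, seed=7,
    )
    return render_pile(pop, (192, 256), overlap=0.0, standing_fraction=0.0)
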
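"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from somamap.synthetic import generate_toy_atlas, generate_scene


@pytest.fixture(scope="session")
def toy_atlas():
    """32^3 atlas, 3 levels: 4 gray-matter leaves + ventricle + fiber tract."""
    return generate_toy_atlas((32, 32, 32), levels=3, regions_per_split=2, seed=7)


@pytest.fixture(scope="session")
def small_scene(toy_atlas):
    """128^3 scene over the 32^3 atlas (upscale 4), ~100 cells."""
    return generate_scene(toy_atlas, upscale=4, cells_per_mm3=30.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
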
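"""Shared fixtures: small seeded synthetic plates and label sets."""

import numpy as np
import pytest

from berrybruise.synthgen import SynthConfig, generate_plate


@pytest.fixture(scope="session")
def small_plate():
    """A quick 6-berry plate with moderate bruising, exact ground truth."""
    cfg = SynthConfig(
        seed=11,
        n_berries=6,
        image_size=420,
        berry_radius_range=(28.0, 40.0),
        bruise_fraction_dist=("uniform", 0.1, 0.3),
        noise_sd=3.0,
    )
    image, berries = generate_plate(cfg)
    return cfg, image, berries


@pytest.fixture(scope="session")
def standard_plate():
    """One plate at the standard study condition: 20 berries, low noise."""
    cfg = SynthConfig(seed=7, n_berries=20)
    image, berries = generate_plate(cfg)
    return cfg, image, berries
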
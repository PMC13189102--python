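import numpy as np
import pytest

from compartquant.sim.images import ImageSimConfig, generate_plate_images


def tiny_image_config(**overrides) -> ImageSimConfig:
    """A fast plate configuration for tests that loop over many seeds."""
    defaults = dict(
        image_size_px=(192, 192),
        n_wells_per_group=1,
        n_cells=2,
        neurites_per_cell=2,
        genotype_effects={"wildtype": {}, "hom_mutant": {"neurite": 2.0}},
    )
    defaults.update(overrides)
    return ImageSimConfig(**defaults)


@pytest.fixture(scope="session")
def default_plate():
    """One plate at the default study conditions, shared across read-only tests."""
    return generate_plate_images(ImageSimConfig(rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
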
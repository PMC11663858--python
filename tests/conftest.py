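import numpy as np
import pytest

import adipoquant as aq


@pytest.fixture(scope="session")
def small_well():
    """A 512x512 well with 80 cells, 30% adipocytes, 10% GFP-on."""
    cfg = aq.SynthConfig(height=512, width=512, n_cells=80,
                         adipocyte_fraction=0.3, gfp_fraction=0.1, seed=3)
    return aq.generate_well(cfg)


@pytest.fixture(scope="session")
def clean_well():
    """Noise-free small well: exact channel levels, no stray intensities."""
    cfg = aq.SynthConfig(height=384, width=384, n_cells=40,
                         adipocyte_fraction=0.5, gfp_fraction=0.2,
                         noise_sd=0.0, oro_noise_sd=0.0, seed=11)
    return aq.generate_well(cfg)


def make_random_instance(rng, shape=(64, 64), n_labels=5):
    """Random (non-connected) label mask + channels for oracle comparisons."""
    cells = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
    droplets = rng.random(shape) < 0.2
    gfp = rng.uniform(0, 255, shape)
    oro = rng.uniform(0, 3, shape)
    return cells, droplets, gfp, oro
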
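import numpy as np
import pytest

from radgen import CohortSpec, generate_tumor_volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_patients=8, grid_size=24, seed=7)


@pytest.fixture(scope="session")
def tumor(small_spec):
    """One metastatic-class synthetic tumor shared across tests."""
    return generate_tumor_volume(small_spec, class_label=1, seed=11)


def random_volume(rng, shape=(6, 6, 6), mask_p=0.8):
    """Random HU cube with a random (guaranteed non-empty) mask."""
    intensities = rng.normal(80, 30, size=shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return intensities, mask
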
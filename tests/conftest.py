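import numpy as np
import pytest

from radharm import CohortSpec, PhantomGeometry, make_phantom
from radharm.synthetic import DEFAULT_PROFILES, apply_centre_effect


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return PhantomGeometry()


@pytest.fixture
def healthy_study(geometry):
    """One canonical-scale healthy phantom."""
    return make_phantom("healthy", geometry, np.random.default_rng(7))


@pytest.fixture
def raw_study(healthy_study):
    """The same phantom after a centre intensity transform."""
    return apply_centre_effect(
        healthy_study, DEFAULT_PROFILES["C3"], np.random.default_rng(8))


def random_roi(rng, shape=(2, 6, 6), n_levels=4, p_mask=0.7):
    """A random discretised ROI instance for oracle comparisons."""
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, int(mask.sum()))
    # ensure the max level is attained so Ng is well defined
    idx = np.argwhere(mask)[0]
    levels[tuple(idx)] = n_levels
    return levels, mask
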
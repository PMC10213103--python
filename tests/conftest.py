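import numpy as np
import pytest

from cbctrad import (
    DEFAULT_PROTOCOLS,
    GridSpec,
    ROIMask,
    generate_mouse_phantom,
    make_spherical_mask,
)


@pytest.fixture(scope="session")
def mouse_phantom():
    """Default 64³ mouse phantom at 0.26 mm (shared across tests)."""
    return generate_mouse_phantom(seed=7)


@pytest.fixture(scope="session")
def soft_tissue_mask(mouse_phantom):
    img, labels, _ = mouse_phantom
    return make_spherical_mask(img.grid, (11.0, 8.3, 8.3), 92.24)


def random_level_volume(rng, max_side=5, max_level=4):
    """Random small ROI: levels 1..Ng on a cuboid with random holes."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    lev = rng.integers(1, max_level + 1, size=shape)
    holes = rng.random(shape) < 0.2
    lev[holes] = 0
    if (lev > 0).sum() == 0:
        lev[0, 0, 0] = 1
    # relabel so levels span 1..Ng exactly
    present = np.unique(lev[lev > 0])
    remap = np.zeros(int(lev.max()) + 1, dtype=np.int64)
    for new, old in enumerate(present, start=1):
        remap[old] = new
    return remap[lev], len(present)
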
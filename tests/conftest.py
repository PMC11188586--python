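import numpy as np
import pytest
from scipy import ndimage

from fibertrack.phantom import build_phantom, make_straight_scene, make_tilted_scene


@pytest.fixture(scope="session")
def straight_phantom():
    """Small noiseless two-fascicle phantom, fibers exactly along z."""
    return build_phantom(make_straight_scene(depth=40, n_fascicles=2, size=160, rng_seed=2))


@pytest.fixture(scope="session")
def tilted_phantom_iso():
    """30-degree tilted fascicle on an isotropic (3 um) grid."""
    spec = make_tilted_scene(
        30.0, depth=40, size=160, pixel_size_xy=3.0, slice_thickness=3.0, rng_seed=2
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def band_limited_texture():
    """Smooth random texture for optic-flow shift-recovery tests."""
    rng = np.random.default_rng(0)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (256, 256)), 3.0)
    return 128.0 + 60.0 * tex / tex.std()
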
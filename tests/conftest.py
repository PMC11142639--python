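import numpy as np
import pytest

from gocquant.synthetic import GOCSpec, generate_goc_2d, generate_goc_3d


@pytest.fixture(scope="session")
def noiseless_2d():
    """A noiseless 40-TZP equatorial section with its truth (shared)."""
    spec = GOCSpec(n_tzp=40, noise_sd=0.0, seed=7)
    image, truth = generate_goc_2d(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_3d():
    """A small two-cell 3D complex with its truth (shared).

    Geometry is scaled down (5 µm oocyte, 2.5 µm zona, ~140 µm³ cells) so
    the stack stays a few million voxels.
    """
    spec = GOCSpec(oocyte_radius=5.0, zona_thickness=2.5, n_tzp=4,
                   tzp_length_mean=2.0, tzp_length_sd=0.3, noise_sd=0.0,
                   image_shape=(60, 340, 340), voxel_size=(0.2, 0.1, 0.1),
                   seed=11)
    channels, truth = generate_goc_3d(spec, n_cells=2, cell_radius=3.2,
                                      cell_radius_sd=0.2)
    return spec, channels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
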
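import numpy as np
import pytest

from petac import (
    PhantomSpec,
    SinogramGeometry,
    VoxelImage,
    centered_grid,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_geom() -> SinogramGeometry:
    """Desk-scale geometry for fast unit tests."""
    return SinogramGeometry(n_angles=60, n_bins=81, bin_width_mm=1.0)


@pytest.fixture(scope="session")
def water_disk():
    """A 50 mm water disk (rat-sized) on a coarse 1 mm single-slice grid."""
    spec = PhantomSpec(
        diameter_mm=50.0,
        length_mm=80.0,
        activity_concentration=1.0,
        grid_shape=(64, 64, 1),
        voxel_mm=(1.0, 1.0, 1.0),
    )
    activity, mu = make_phantom(spec)
    return spec, activity, mu


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_image(rng, shape=(32, 32), spacing=1.0) -> VoxelImage:
    img = centered_grid(shape + (1,), spacing)
    return img.with_values(rng.random(shape)[:, :, None])
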
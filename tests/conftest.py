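import logging

import numpy as np
import pytest

from angioqa.phantom import PhantomSpec, build_vessel_tree, rasterize

logging.disable(logging.WARNING)  # partial-volume warnings are expected on perforators


@pytest.fixture(scope="session")
def tree_small():
    """Default five-level tree in a compact extent (all caliber classes)."""
    return build_vessel_tree(seed=1, n_branch_levels=5, extent_mm=(36.0, 36.0, 22.0))


@pytest.fixture(scope="session")
def spec_small():
    return PhantomSpec(grid_shape=(72, 72, 44), voxel_size=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def clean_small(tree_small, spec_small):
    """Noiseless rasterization used by registration and metric tests."""
    return rasterize(tree_small, spec_small, subsamples=4)


@pytest.fixture(scope="session")
def mip_fine(tree_small):
    """A fine-voxel MIP of the small tree, normalized to [0, 1]."""
    from angioqa.edges import mip

    spec = PhantomSpec(grid_shape=(180, 180, 44), voxel_size=(0.2, 0.2, 0.5))
    vol = rasterize(tree_small, spec, subsamples=4)
    img = mip(vol, "axial").data
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
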
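from __future__ import annotations

import numpy as np
import pytest

from wmh_subclass.volumes_io import BinaryMask, VoxelGrid


def make_grid(data, voxel_dims=(1.0, 1.0, 1.0), space_tag="test") -> VoxelGrid:
    affine = np.diag(list(voxel_dims) + [1.0])
    return VoxelGrid(np.asarray(data), affine=affine, space_tag=space_tag)


def make_mask(data, voxel_dims=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(make_grid(np.asarray(data).astype(np.uint8), voxel_dims))


def random_mask(rng: np.random.Generator, shape=(10, 10, 10), density=0.3) -> BinaryMask:
    return make_mask(rng.random(shape) < density)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    """A modest phantom spec that renders quickly."""
    from wmh_subclass.phantom import PhantomSpec

    return PhantomSpec(
        shape=(32, 32, 32),
        brain_semi_axes=(13.0, 14.0, 13.0),
        ventricle_semi_axes=(2.5, 6.0, 3.0),
        ventricle_offset=5.0,
        n_peri_lesions=3,
        n_deep_lesions=3,
        lesion_median_voxels=12.0,
        seed=7,
    )
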
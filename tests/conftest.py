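import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles` and `helpers`

from dabsms.volumes import AtlasBundle, CubeGrid, ImageVolume, MaskVolume


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def grid8():
    return CubeGrid(side=8, voxel_size=1.0)


@pytest.fixture()
def random_volume8(rng, grid8):
    return ImageVolume(voxels=rng.standard_normal(grid8.shape), spacing=grid8.spacing)


@pytest.fixture()
def blob_mask8(grid8):
    m = np.zeros(grid8.shape, dtype=np.uint8)
    m[2:6, 2:6, 2:6] = 1
    return MaskVolume(voxels=m, spacing=grid8.spacing)


@pytest.fixture()
def bundle8(random_volume8, blob_mask8):
    return AtlasBundle(image=random_volume8, transfer_mask=blob_mask8)


@pytest.fixture(scope="session")
def recovery_run():
    """The scaled-down end-to-end recovery experiment (expensive; shared)."""
    from helpers import run_recovery

    return run_recovery(seed=1)
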
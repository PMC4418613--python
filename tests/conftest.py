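import numpy as np
import pytest

from thymoshape import VoxelMask, PhantomSpec, make_phantom


@pytest.fixture
def cube3() -> VoxelMask:
    """3x3x3 solid cube at 1 mm spacing."""
    return VoxelMask(np.ones((3, 3, 3), dtype=np.uint8))


@pytest.fixture
def rod8() -> VoxelMask:
    """1x1x8 straight rod at 1 mm spacing."""
    return VoxelMask(np.ones((1, 1, 8), dtype=np.uint8))


@pytest.fixture
def single_voxel() -> VoxelMask:
    return VoxelMask(np.ones((1, 1, 1), dtype=np.uint8))


@pytest.fixture
def sphere_factory():
    """Digital sphere of a given radius (voxel centers inside surface)."""
    def make(radius: int, spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
        mask = make_phantom(PhantomSpec(kind="sphere", radius=radius,
                                        spacing=spacing))
        return mask
    return make


@pytest.fixture
def cystic_cohort():
    """53-subject cohort realizing the published cystic-change 2x2 counts.

    Encapsulated: 3 of 23 with cystic change; invasive: 16 of 30.
    """
    import pandas as pd
    rows = []
    for i in range(23):
        rows.append(dict(subject_id=f"E{i:02d}", label=0,
                         cystic_change=int(i < 3)))
    for i in range(30):
        rows.append(dict(subject_id=f"I{i:02d}", label=1,
                         cystic_change=int(i < 16)))
    return pd.DataFrame(rows)
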
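import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from zeonco.io import VoxelStack
from zeonco.synthetic import SyntheticLarvaSpec


@pytest.fixture
def small_spec() -> SyntheticLarvaSpec:
    """A compact larva (fast to render) with the standard intensity model."""
    return SyntheticLarvaSpec(
        larva_id="L001",
        grid_shape=(30, 80, 160),
        voxel_size=(2.0, 1.0, 1.0),
        primary_center=(30.0, 40.0, 70.0),
        primary_semi_axes=(10.0, 12.0, 12.0),
        eye_center=(30.0, 40.0, 20.0),
        eye_radius=8.0,
        foci_x_offset=60.0,
        foci_x_spread=8.0,
        foci_y_jitter=6.0,
        foci_radius=5.0,
        growth_factor=2.0,
        noise_sd=2.0,
        seed=11,
    )


def make_stack(arr, voxel_size=(1.0, 1.0, 1.0), **kwargs) -> VoxelStack:
    return VoxelStack(np.asarray(arr, dtype=float), voxel_size, **kwargs)
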
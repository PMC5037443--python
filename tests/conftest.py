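import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cartt2.laminar import CartilageSegmentation
from cartt2.synthetic import (
    PhantomSpec,
    SlabPlate,
    default_phantom_spec,
    generate_phantom,
)

ECHO_TIMES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)


def make_column_segmentation(thickness: int = 10) -> CartilageSegmentation:
    """A single 1-voxel-wide cartilage column: surface on top, bone below."""
    shape = (1, thickness + 4, 5)
    mask = np.zeros(shape, dtype=bool)
    bone = np.zeros(shape, dtype=bool)
    surf = np.zeros(shape, dtype=bool)
    mask[0, 2 : 2 + thickness, 2] = True
    surf[0, 2, 2] = True
    bone[0, 2 + thickness - 1, 2] = True
    return CartilageSegmentation(
        plate_masks={"MT": mask}, bone_interface=bone, surface=surf,
        voxel_spacing_mm=(3.0, 0.3125, 0.3125),
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Four-plate step-profile phantom at healthy plate T2 levels, no noise."""
    spec = default_phantom_spec(n_slices=1, noise_sd=0.0)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def slab_spec():
    """Minimal one-slab phantom spec (thickness 10, step profile)."""
    return PhantomSpec(
        plate_shapes={"MT": SlabPlate(origin=(0, 2, 2), thickness=10, length=20)},
        volume_shape=(1, 16, 26),
        t2_deep_ms=35.8,
        t2_superficial_ms=45.4,
        t2_profile="step",
        noise_sd=0.0,
        seed=0,
    )
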
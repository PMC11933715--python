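import numpy as np
import pytest

from musclevol import PhantomSpec, profile_from_volume, reference_volume, voxelize

STD_SPACING = (0.65, 0.65, 2.0)


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Voxelized cylinder, L = 300 mm, A = 2000 mm^2, MRI-like spacing."""
    spec = PhantomSpec.cylinder(300.0, 2000.0)
    return spec, voxelize(spec, STD_SPACING)


@pytest.fixture(scope="session")
def cone_phantom():
    """Voxelized cone (apex distal), L = 300 mm, A_max = 2000 mm^2."""
    spec = PhantomSpec.cone(300.0, 2000.0)
    return spec, voxelize(spec, STD_SPACING)


@pytest.fixture(scope="session")
def spindle_phantom():
    """Symmetric beta spindle (x_m = 0.5, kappa = 2), L = 300, A_max = 2000."""
    spec = PhantomSpec.beta_spindle(300.0, 2000.0, peak_location=0.5, sharpness=2.0)
    return spec, voxelize(spec, STD_SPACING)


@pytest.fixture(scope="session")
def spindle_profile(spindle_phantom):
    _, vol = spindle_phantom
    return profile_from_volume(vol)


@pytest.fixture(scope="session")
def cylinder_profile(cylinder_phantom):
    _, vol = cylinder_phantom
    return profile_from_volume(vol)


@pytest.fixture(scope="session")
def cone_profile(cone_phantom):
    _, vol = cone_phantom
    return profile_from_volume(vol)
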
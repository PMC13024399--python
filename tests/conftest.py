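import numpy as np
import pytest

from myomap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free transmural-lesion phantom spec on a small grid."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_size=(1.5, 1.5, 1.5),
        noise_sd=0.0,
        lesion_kind="transmural",
        territory="RCA",
        lesion_hu_offset=-80.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def quiet_case(quiet_spec):
    return generate_phantom(quiet_spec)


@pytest.fixture(scope="session")
def shell_mask(quiet_case):
    """A realistic myocardial shell of several thousand voxels."""
    return quiet_case.myo_mask_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
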
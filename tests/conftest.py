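import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from locrad.io import ImageVolume, LesionMask
from locrad.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_patient():
    """One significant-class phantom patient (fast, deterministic)."""
    cfg = CohortConfig(n_ncs=1, n_cs=1, seed=11)
    return generate_cohort(cfg)[1]


@pytest.fixture()
def toy_volume(rng):
    """A random 3-slice volume with an off-center box mask."""
    vox = rng.normal(100.0, 10.0, size=(3, 15, 14))
    mask = np.zeros_like(vox, dtype=np.uint8)
    mask[1, 4:9, 5:10] = 1
    vol = ImageVolume(voxels=vox, pixel_spacing_mm=(1.5, 1.5), slice_thickness_mm=3.0)
    return vol, LesionMask(voxels=mask)
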
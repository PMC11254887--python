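import pytest

from splitgfr.core import AcquisitionMeta, PatientInfo
from splitgfr.phantom import sample_scene, simulate_renogram


@pytest.fixture
def patient() -> PatientInfo:
    return PatientInfo(age=50, sex="male", weight_kg=70.0, height_cm=170.0)


@pytest.fixture
def meta() -> AcquisitionMeta:
    return AcquisitionMeta()


@pytest.fixture
def scene():
    """One deterministic, geometrically valid phantom scene."""
    return sample_scene(42, gfr_range=(60.0, 60.0), split_range=(0.55, 0.55))


@pytest.fixture
def noiseless_scan(scene):
    return simulate_renogram(scene.patient, scene.truth, scene.meta, noise=False)


@pytest.fixture
def noisy_scan(scene):
    return simulate_renogram(scene.patient, scene.truth, scene.meta, noise=True, rng_seed=7)
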
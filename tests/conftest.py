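import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fsid.core import Task
from fsid.simulate import MovementProfile, default_profiles, generate_cohort, generate_task


@pytest.fixture(scope="session")
def healthy_profile():
    return default_profiles()[0]


@pytest.fixture(scope="session")
def fs_profile():
    return default_profiles()[1]


@pytest.fixture(scope="session")
def healthy_recording(healthy_profile):
    """One seeded healthy washing-hair task recording."""
    return generate_task(Task.WH, healthy_profile, seed=7)


@pytest.fixture(scope="session")
def fs_recording(fs_profile):
    return generate_task(Task.WH, fs_profile, seed=7)


@pytest.fixture(scope="session")
def noiseless_profile():
    """Single smooth stroke, no sensor noise: analytic trajectory shapes."""
    return MovementProfile(
        amplitude_scale=1.0, duration_scale=1.0, n_submovements=1,
        tremor_sd=0.0, gyro_noise_sd=0.0, hold_oscillation_amp=0.1,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 FS + 4 healthy subjects: enough structure for fold/experiment tests."""
    return generate_cohort(4, 4, seed=11)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    from fsid.features import extract_cohort_features

    return extract_cohort_features(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
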
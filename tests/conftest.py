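import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hipfatigue as hf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_semg_params():
    """Desk-scale sEMG synthesis: 30 s at 1 kHz, fatigue slope -0.4 %/s."""
    return hf.SemgSynthParams(
        duration_s=30.0,
        fs_emg=1000.0,
        center_freq0=110.0,
        rel_mnf_slope=-0.004,
        bandwidth=50.0,
        amp0=1e-4,
        rel_amp_slope=0.002,
        noise_floor=1e-6,
        seed=7,
    )


@pytest.fixture
def small_accel_params():
    return hf.AccelSynthParams(duration_s=30.0, fs_imu=100.0, seed=7)


@pytest.fixture
def small_cohort_spec(small_semg_params, small_accel_params):
    """12-trial cohort with a mix of responders and non-responders."""
    return hf.CohortSpec(
        n_subjects=6,
        activities=("wall_sit", "single_leg_squat"),
        responder_fraction=0.6,
        master_seed=11,
        semg=small_semg_params,
        accel=small_accel_params,
    )


@pytest.fixture
def small_feature_config():
    return hf.FeatureConfig()


@pytest.fixture(scope="session")
def small_feature_tables():
    """Raw + normalized feature tables for a 12-trial desk-scale cohort."""
    semg = hf.SemgSynthParams(
        duration_s=30.0, fs_emg=1000.0, center_freq0=110.0, rel_mnf_slope=-0.004,
        bandwidth=50.0, noise_floor=1e-6, seed=7,
    )
    accel = hf.AccelSynthParams(duration_s=30.0, fs_imu=100.0, seed=7)
    spec = hf.CohortSpec(
        n_subjects=6, activities=("wall_sit", "single_leg_squat"),
        responder_fraction=0.6, master_seed=11, semg=semg, accel=accel,
    )
    from hipfatigue.features import build_feature_table, normalize
    from hipfatigue.synthetic import cohort_truth, iter_cohort

    truth = cohort_truth(spec)
    raw = build_feature_table(iter_cohort(spec, truth), hf.FeatureConfig(normalize=False))
    norm = normalize(raw, "subject")
    return raw, norm, truth
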
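import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny noiseless cohort shared by detection / sync / pipeline tests."""
    from tapagree.signal_model import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_subjects=3,
        n_hands=2,
        n_trials_per_hand=2,
        noise_sd_frac=0.0,
        artifact_prob=0.0,
        seed=42,
    )
    return generate_cohort(cfg)
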
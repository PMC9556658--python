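import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 16-subject cohort (1 session x 300 trials, blocks of 100)."""
    from choicehist.synthetic import generate_cohort

    trials, signals, agents = generate_cohort(
        n_subjects=16, repeater_fraction=0.5, trials_per_session=300,
        n_sessions=1, block_size=100, seed=20240)
    return trials, signals, agents


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
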
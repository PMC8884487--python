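import numpy as np
import pytest
from hypothesis import settings

from tonescene.envelope import EnvelopeParams
from tonescene.erb import place_tones
from tonescene.neuro import CohortSpec, ResponseModelParams, simulate_cohort
from tonescene.stimulus import CoherenceSchedule, make_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: audio rate used throughout the tests; cheaper than the 48-kHz production
#: default while still clearing the 8-kHz carriers comfortably
TEST_AUDIO_RATE = 24000.0


@pytest.fixture(scope="session")
def bank():
    return place_tones(20, 200.0, 8000.0, 60.0)


@pytest.fixture(scope="session")
def env_params():
    return EnvelopeParams()


@pytest.fixture(scope="session")
def trial_n18(bank, env_params):
    sched = CoherenceSchedule.random_subset(18, 20, np.random.default_rng(42))
    return make_trial(bank, env_params, sched, seed=42, audio_rate_hz=TEST_AUDIO_RATE)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-participant cohort at reduced trial count, default effect sizes."""
    spec = CohortSpec(
        n_td=6, n_asd=4, trials_per_condition=12,
        epoch_window_s=(-0.3, 0.8), master_seed=2024,
    )
    return simulate_cohort(spec, ResponseModelParams())
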
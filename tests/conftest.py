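import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vowelvar as vv
from vowelvar.synth import DEFAULT_VOWEL_TARGETS

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def vowel_targets():
    return DEFAULT_VOWEL_TARGETS


@pytest.fixture(scope="session")
def steady_eh_trial():
    """A steady /eh/ token (no offsets, no drift) with ground truth."""
    return vv.synthesize_vowel(DEFAULT_VOWEL_TARGETS[2], seed=11)


@pytest.fixture(scope="session")
def tracked_eh(steady_eh_trial):
    return vv.track_formants(steady_eh_trial.waveform)


@pytest.fixture(scope="session")
def small_cohort_config():
    """4 participants x 4 vowels x 2 conditions x 2 trials = 64 audio trials."""
    return vv.CohortConfig(n_per_group=2, trials_per_vowel_per_condition=2, seed=7)


@pytest.fixture(scope="session")
def balanced_table():
    """Default-design (24 participants) simulated per-cell log-TTV table."""
    return vv.simulate_log_ttv_table(n_per_group=12, rng=5)
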
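import numpy as np
import pytest

import swayrisk as sr


@pytest.fixture(scope="session")
def small_spec():
    return sr.CohortSpec(n_participants=12, seed=7, sampling_rate=90.0)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sr.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_spec, small_cohort):
    participants, trials = small_cohort
    table, log = sr.build_feature_table(participants, trials)
    return table


@pytest.fixture(scope="session")
def medium_table():
    """A 40-participant feature table, large enough to stratify both labels."""
    spec = sr.CohortSpec(n_participants=40, seed=21)
    participants, trials = sr.generate_cohort(spec)
    table, _ = sr.build_feature_table(participants, trials)
    return table


@pytest.fixture(scope="session")
def planted():
    """Planted-feature table at the recovery-experiment scale."""
    return sr.make_planted_table(n_samples=300, seed=11)


def sinusoid_trial(freq=0.5, amp_ap=10.0, amp_ml=0.0, fs=90.0, duration=30.0):
    """A deterministic sinusoidal trial for closed-form feature checks."""
    t = np.arange(int(round(duration * fs))) / fs
    return sr.SwayTrial(
        participant_id="T",
        condition="W-EO",
        trial_index=1,
        t=t,
        ml=amp_ml * np.sin(2 * np.pi * freq * t),
        ap=amp_ap * np.sin(2 * np.pi * freq * t),
    )
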
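import numpy as np
import pytest

from sleepbelt import synthetic as syn


@pytest.fixture(scope="session")
def clean_subject():
    return syn.SubjectSpec("clean", ahi=0.0, base_hr=60.0, base_bf=14.0,
                           noise_level=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_ecg(clean_subject):
    """10-minute noise-free 60-bpm ECG with ground truth."""
    return syn.synthesize_ecg(clean_subject, [], fs=250.0, duration=600.0)


@pytest.fixture(scope="session")
def clean_excursion(clean_subject):
    """10-minute noise-free 14-breaths/min excursion trace."""
    return syn.synthesize_excursion(clean_subject, [], fs=25.0, duration=600.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
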
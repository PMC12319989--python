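import numpy as np
import pytest

from tdcsdose import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3 x 5 cohort with full-size EMG, no EEG; shared across tests."""
    cfg = synth.CohortConfig(n_per_group=5, seed=42)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def eeg_cohort():
    """Tiny cohort with EEG epochs for TEP-pipeline tests."""
    cfg = synth.CohortConfig(
        n_per_group=4, seed=7, mep_n_trials=35, include_eeg=True,
        eeg_n_trials=8, eeg_channels=tuple(synth.DEFAULT_EEG_CHANNELS[7:24]),
    )
    return synth.generate_cohort(cfg)
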
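import numpy as np
import pytest

from neurofuse.microstate import compute_gfp, extract_gfp_peaks
from neurofuse.synthetic import (
    CohortConfig,
    EEGSimConfig,
    gen_cohort_features,
    gen_microstate_eeg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_cohort():
    """Study-sized cohort (19 NA / 22 NCD) with 10 planted features per modality."""
    table, truth = gen_cohort_features(CohortConfig(effect_size=1.5, seed=42))
    return table, truth


@pytest.fixture(scope="session")
def sim_eeg_5min():
    """One 5-minute 64-channel 4-state record at SNR 4, with ground truth."""
    rec, truth = gen_microstate_eeg(EEGSimConfig(duration=300.0, snr=4.0, seed=7))
    return rec, truth


@pytest.fixture(scope="session")
def sim_eeg_peaks(sim_eeg_5min):
    rec, truth = sim_eeg_5min
    gfp = compute_gfp(rec)
    _, maps = extract_gfp_peaks(gfp, rec, n_peaks=1000)
    return rec, truth, gfp, maps
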
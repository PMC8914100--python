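import numpy as np
import pytest

from isapac import SyntheticConfig, gen_session, preprocess_recording


@pytest.fixture(scope="session")
def small_session():
    """One coupled synthetic session at a reduced generation rate.

    4 Hz generation keeps the filter/Hilbert chain honest (the analysis
    still decimates to 1 Hz afterwards) while staying fast enough to share
    across tests.
    """
    cfg = SyntheticConfig(duration=2400.0, fs=4.0, n_eeg=4, m=1.0,
                          reset_kappa=8.0, n_trials=25, seed=42)
    rec, truth = gen_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_session):
    cfg, rec, truth = small_session
    return cfg, truth, preprocess_recording(rec)


def tone(f, fs, duration, amp=1.0, kind="cos"):
    t = np.arange(int(round(duration * fs))) / fs
    fn = np.cos if kind == "cos" else np.sin
    return t, amp * fn(2 * np.pi * f * t)
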
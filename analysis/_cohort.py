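"""Shared cohort definition for the numbered analysis scripts.

The study design: 24 synthetic subjects, 12 with strong infraslow-GSR
coupling and onset phase reset ("coupled") and 12 with neither
("uncoupled").  Everything is regenerated deterministically from the
per-subject seeds in results/cohort.tsv, so no bulky intermediate data
needs to be stored between scripts.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isapac import SyntheticConfig, gen_session, preprocess_recording

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_PER_GROUP = 12
N_EEG = 8
DURATION = 2400.0
GEN_FS = 4.0
N_TRIALS = 25
COHORT_SEED = 20_260_920


def build_cohort_table() -> pd.DataFrame:
    rng = np.random.default_rng(COHORT_SEED)
    rows = []
    for i in range(2 * N_PER_GROUP):
        coupled = i < N_PER_GROUP
        rows.append({
            "subject": f"sub-{i:02d}",
            "coupled": coupled,
            "m": 1.0 if coupled else 0.0,
            "reset_kappa": 8.0 if coupled else 0.0,
            "phi_pref": float(rng.uniform(-np.pi, np.pi)),
            "seed": int(rng.integers(0, 2**31 - 1)),
        })
    return pd.DataFrame(rows)


def load_cohort_table() -> pd.DataFrame:
    path = RESULTS / "cohort.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run analysis/01_simulate.py first")
    return pd.read_csv(path, sep="\t")


def config_for(row) -> SyntheticConfig:
    return SyntheticConfig(
        duration=DURATION, fs=GEN_FS, n_eeg=N_EEG, n_trials=N_TRIALS,
        m=float(row["m"]), reset_kappa=float(row["reset_kappa"]),
        phi_pref=float(row["phi_pref"]), seed=int(row["seed"]),
    )


def preprocessed_for(row):
    rec, truth = gen_session(config_for(row))
    return preprocess_recording(rec), truth
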
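"""Median split by d-prime and group comparisons over the epoch.

Subjects are split into high/low groups at the median channel-average
d-prime (from results/pac_subjects.tsv).  Per time point of the 30-s
epoch the groups are compared on: ITPC (two-sided t-test over subject x
channel samples), median instantaneous frequency (plus the one-sided
decrease-vs-first-10-s test within each group), and the mean GSR
amplitude trace (mean +- SEM only).

Writes results/group_split.json and results/group_timecourses.tsv.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from _cohort import N_EEG, RESULTS, load_cohort_table, preprocessed_for
from isapac import (baseline_decrease_test, extract_epochs, median_split,
                    subject_itpc, timepoint_group_test)

cohort = load_cohort_table()
pac = pd.read_csv(RESULTS / "pac_subjects.tsv", sep="\t")
split = median_split(dict(zip(pac.subject, pac.mean_dprime)))
designed = dict(zip(cohort.subject, cohort.coupled))
agree = (all(designed[s] for s in split.group_a)
         and not any(designed[s] for s in split.group_b))
(RESULTS / "group_split.json").write_text(json.dumps({
    "criterion": split.criterion,
    "high": split.group_a, "low": split.group_b,
    "matches_designed_groups": agree}, indent=2))
print(f"median split: {len(split.group_a)} high / {len(split.group_b)} low"
      f"; matches the designed coupled/uncoupled assignment: {agree}")

itpc, freq, gsr = {}, {}, {}
for _, row in cohort.iterrows():
    pre, _ = preprocessed_for(row)
    sid = row["subject"]
    itpc[sid] = np.vstack([subject_itpc(pre, c).itpc_t
                           for c in range(N_EEG)])
    freq[sid] = np.vstack([
        np.median(extract_epochs(pre.eeg_freq[c], pre.trial_onsets,
                                 fs=pre.fs).values, axis=0)
        for c in range(N_EEG)])
    gsr[sid] = extract_epochs(pre.gsr_amp, pre.trial_onsets,
                              fs=pre.fs).values.mean(axis=0)

t = np.arange(31.0)
out = []


def stack(d, ids):
    return np.vstack([d[s] for s in ids])


for name, store in (("itpc", itpc), ("inst_freq", freq)):
    a, b = stack(store, split.group_a), stack(store, split.group_b)
    p, mask = timepoint_group_test(a, b)
    for j, tj in enumerate(t):
        out.append({"variable": name, "t": tj,
                    "high_mean": round(float(a[:, j].mean()), 5),
                    "high_sem": round(float(a[:, j].std(ddof=1)
                                            / np.sqrt(a.shape[0])), 5),
                    "low_mean": round(float(b[:, j].mean()), 5),
                    "low_sem": round(float(b[:, j].std(ddof=1)
                                           / np.sqrt(b.shape[0])), 5),
                    "p_group": round(float(p[j]), 6),
                    "sig_group": bool(mask[j])})
    if name == "itpc":
        n_sig_early = int(mask[:11].sum())
        print(f"ITPC group test: {n_sig_early}/11 time points in 0-10 s "
              f"significant (high > low: {a[:, :11].mean() > b[:, :11].mean()})")

# GSR epoch traces: mean +- SEM only, no test
ga, gb = stack(gsr, split.group_a), stack(gsr, split.group_b)
for j, tj in enumerate(t):
    out.append({"variable": "gsr_amp", "t": tj,
                "high_mean": round(float(ga[:, j].mean()), 5),
                "high_sem": round(float(ga[:, j].std(ddof=1)
                                        / np.sqrt(ga.shape[0])), 5),
                "low_mean": round(float(gb[:, j].mean()), 5),
                "low_sem": round(float(gb[:, j].std(ddof=1)
                                       / np.sqrt(gb.shape[0])), 5),
                "p_group": np.nan, "sig_group": False})

# within-group frequency decrease vs the first 10 s
for label, ids in (("high", split.group_a), ("low", split.group_b)):
    pdec, mdec, idx = baseline_decrease_test(stack(freq, ids), t)
    print(f"frequency decrease vs first 10 s ({label} group): "
          f"{int(mdec.sum())}/{idx.size} later time points flagged")

df = pd.DataFrame(out)
df.to_csv(RESULTS / "group_timecourses.tsv", sep="\t", index=False)
print("wrote results/group_timecourses.tsv")
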
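# isapac

Phase–amplitude coupling between infraslow EEG activity and peripheral
arousal signals.

Infraslow activity (ISA, 0.01–0.1 Hz) is the slowest electrical rhythm
measurable in human EEG. A recurring observation is that the *phase* of
this rhythm organizes other physiology: skin conductance (GSR, a
sympathetic-arousal readout) tends to be larger at particular ISA phases,
and trial onsets partially reset the ISA phase. `isapac` implements the
complete analysis chain for testing such claims on multichannel
recordings (EEG + GSR + respiration with trial events), together with a
fully parameterized synthetic-session generator so every stage can be
validated against known ground truth.

## What it computes

For each EEG channel with instantaneous ISA phase θ(t) and a peripheral
amplitude series a(t), both at 1 Hz:

* **Phase-binned coupling** — θ is divided into 8 bins over (−π, π];
  the bins with maximal/minimal median a are compared by the
  discriminability index

  d′ = |μ₁ − μ₂| / ((σ₁ + σ₂)/2)

  plus a two-sample t-test, yielding a preferred coupling phase φ_max
  per channel (for sinusoidal coupling, φ_max − φ_min ≈ π).
* **Phase coherence** — the mean-resultant length R = |N⁻¹ Σ exp(iθₙ)|
  across channels (ICPC) or across trials at each post-onset second
  (ITPC), the latter with a timing-permutation null (phases drawn from
  random time points of the recording, 10⁴ permutations).
* **Lag scans** — the phase-locking value between EEG ISA phase and the
  ISA-band phase of a peripheral amplitude envelope, maximized over lags
  ±60 s, against a randomized-phase 95% reference level.
* **Group comparisons** — median split of subjects by channel-average
  d′, per-time-point group t-tests of ITPC / instantaneous frequency /
  GSR epochs, and a one-sided decrease test against the first-10-s
  baseline.

Preprocessing follows the band's constraints: zero-phase Butterworth
filtering and Hilbert transform at the native rate (256 Hz for BioSemi
data), decimation to 1 Hz afterwards, with 100 s edge guards excluded
from all statistics. EDF/BDF recordings and BIDS-style `*_events.tsv`
tables are read via MNE; a minimal 16-bit EDF writer is included for the
synthetic sessions. See `docs/methods.md` for conventions and caveats.

## Worked example

```python
import numpy as np
from isapac import (SyntheticConfig, gen_session, preprocess_recording,
                    run_subject_pac, lag_scan, subject_itpc)

cfg = SyntheticConfig(duration=2400, fs=4, n_eeg=4, m=1.0,
                      reset_kappa=8.0, n_trials=25, seed=11)
rec, truth = gen_session(cfg)          # 4 EEG + GSR + RESP channels
pre = preprocess_recording(rec)        # 1 Hz phase/amplitude series

results, summary, table = run_subject_pac(pre)   # PAC vs GSR amplitude
print(round(summary.mean_dprime, 2), round(summary.mean_phi_max, 2),
      round(float(np.mean(np.abs(summary.phase_diff))), 2))
# 9.34 -0.39 2.95

g = lag_scan(pre.eeg_phase[0], pre.gsr_phase, valid=pre.valid, n_null=0)
r = lag_scan(pre.eeg_phase[0], pre.resp_phase, valid=pre.valid, n_null=0)
print(g.best_lag, r.best_lag)
# 0.0 10.0

s = subject_itpc(pre, 0)               # 30-s post-onset ITPC time course
print(round(float(s.itpc_t[0]), 2), round(float(s.itpc_t[-1]), 2))
# 0.64 0.07
```

The generator plants coupling at preferred phase 0 with full modulation
depth: the recovered mean d′ of 9.34 is far above the ≈0.1 uncoupled
selection floor, the preferred phase −0.39 rad is the bin centre nearest
the designed 0 (bins are π/4 wide), and the max–min phase separation of
2.95 rad is within a bin width of π. The designed GSR lag (0 s) and
respiration lag (10 s) are
recovered exactly, and the onset phase reset shows as ITPC decaying from
0.64 at the trial onset to 0.07 at 30 s.

## Analysis scripts

`analysis/01_simulate.py` … `05_group_comparison.py` run the full
synthetic study — a 24-subject cohort (12 coupled with onset resets, 12
uncoupled) — through spectral checks, per-channel PAC, lag scans, ITPC
with permutation nulls, and the median-split group comparison, writing
tidy TSV tables under `results/`. Each script prints a one-paragraph
summary of what it found; run them in order from the repository root.

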
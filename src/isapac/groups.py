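"""Epoching and group-level comparisons.

Epochs are the first 30 s after each trial onset on the 1 Hz analysis
grid, inclusive of both endpoints (31 time points).  Group machinery:

* median split of subjects by channel-average d-prime (top half = "high"),
* per-time-point two-sample t-tests pooling subject x channel samples
  (for a full 12-subject, 64-channel group that is 768 samples per time
  point), and
* a one-sided decrease test of instantaneous frequency at each later time
  point against the mean over the first 10 s baseline window.

Pooling channels as independent samples follows the convention of the
analysis this package reproduces; a subject-level (channel-averaged)
variant is available via the ``pool`` argument for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "EpochSet",
    "GroupSplit",
    "extract_epochs",
    "median_split",
    "timepoint_group_test",
    "baseline_decrease_test",
]


@dataclass
class EpochSet:
    """Trials x time values of one variable, aligned to trial onsets.

    The time axis has ``epoch_len * fs + 1`` points (t = 0 .. epoch_len,
    both ends included) — fixed once here and used everywhere.
    """

    values: np.ndarray
    t: np.ndarray
    variable: str = ""
    subject_id: str = ""
    channel: str = ""

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def extract_epochs(x, onsets, epoch_len: float = 30.0, fs: float = 1.0,
                   variable: str = "", subject_id: str = "",
                   channel: str = "") -> EpochSet:
    """Cut onset-aligned epochs out of a series at rate ``fs``.

    Onsets whose epoch would run past the end of the recording are dropped
    with a warning; zero surviving trials is an error.
    """
    x = np.asarray(x, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    n_t = int(round(epoch_len * fs)) + 1
    rows, dropped = [], 0
    for on in onsets:
        i0 = int(round(on * fs))
        if i0 < 0 or i0 + n_t > x.size:
            dropped += 1
            continue
        rows.append(x[i0:i0 + n_t])
    if dropped:
        warnings.warn(f"{dropped} onset(s) too close to the recording end; "
                      "dropped", stacklevel=2)
    if not rows:
        raise ValueError("no onset leaves room for a full epoch")
    return EpochSet(values=np.vstack(rows), t=np.arange(n_t) / fs,
                    variable=variable, subject_id=subject_id, channel=channel)


@dataclass
class GroupSplit:
    group_a: list[str]   # high group
    group_b: list[str]   # low group
    criterion: str

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")


def median_split(subject_dprimes: dict[str, float],
                 tie_break_seed: int | None = None) -> GroupSplit:
    """Split subjects into high/low halves by channel-average d-prime.

    Subjects are ranked by value (descending), ties broken by subject id,
    and the top half (n // 2 for odd n: strictly-above-median subjects)
    forms the high group.  If every value is identical the split is
    undefined; a ``tie_break_seed`` then randomizes the assignment,
    otherwise an error is raised.
    """
    if len(subject_dprimes) < 2:
        raise ValueError("median split needs at least 2 subjects")
    items = list(subject_dprimes.items())
    values = np.array([v for _, v in items], dtype=float)
    if np.ptp(values) == 0.0:
        if tie_break_seed is None:
            raise ValueError("split undefined under ties: all d-prime "
                             "values equal (provide tie_break_seed)")
        rng = np.random.default_rng(tie_break_seed)
        order = rng.permutation(len(items))
        ranked = [items[i][0] for i in order]
    else:
        ranked = [sid for sid, _ in
                  sorted(items, key=lambda kv: (-kv[1], kv[0]))]
    k = len(ranked) // 2
    return GroupSplit(group_a=ranked[:k], group_b=ranked[k:],
                      criterion="median channel-average d-prime")


def timepoint_group_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                         equal_var: bool = False,
                         alternative: str = "two-sided"):
    """Two-sample t-test at each time point between groups A and B.

    ``a`` and ``b`` are samples x time arrays pooling the per-(subject,
    channel) values of each group.  Returns (p_values, significance mask).
    Time points where both groups are degenerate (zero variance, equal
    means included) get p = 1 with a warning.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the time axis")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = _stats.ttest_ind(a, b, axis=0, equal_var=equal_var,
                               alternative=alternative)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(f"degenerate variance at {int(bad.sum())} time "
                      "point(s); p set to 1", stacklevel=2)
        p[bad] = 1.0
    return p, p < alpha


def baseline_decrease_test(values: np.ndarray, t: np.ndarray,
                           baseline_window: float = 10.0,
                           alpha: float = 0.05, paired: bool = False):
    """One-sided decrease test vs. the early-epoch baseline.

    ``values`` is samples x time (one row per subject-channel median
    trace); the baseline is each row's mean over t < ``baseline_window``.
    Each later time point is tested for a *decrease* relative to baseline
    — unpaired two-sample by default, paired (per-row differences) when
    ``paired=True``.  Returns (p per later t, mask, later-t indices).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.asarray(t, dtype=float)
    base_cols = t < baseline_window
    test_cols = np.flatnonzero(~base_cols)
    if not base_cols.any() or test_cols.size == 0:
        raise ValueError("epoch must cover the baseline window and beyond")
    baseline = values[:, base_cols].mean(axis=1)
    later = values[:, test_cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        if paired:
            res = _stats.ttest_1samp(later - baseline[:, None], 0.0,
                                     axis=0, alternative="less")
        else:
            res = _stats.ttest_ind(later, baseline[:, None], axis=0,
                                   equal_var=False, alternative="less")
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(f"degenerate variance at {int(bad.sum())} time "
                      "point(s); p set to 1", stacklevel=2)
        p[bad] = 1.0
    return p, p < alpha, test_cols
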
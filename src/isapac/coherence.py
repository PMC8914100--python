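"""Phase coherence across channels and trials, with permutation nulls.

Two uses of the same resultant-length statistic:

* ICPC (inter-channel phase coherence): |mean_n exp(i theta_n)| over
  channels' phases at matched definition points (e.g., each channel's
  preferred coupling phase).
* ITPC (inter-trial phase coherence): the same statistic over trials at a
  fixed time t after trial onset; values near 1 indicate the oscillation's
  phase is reset by the trial event.

Significance of ITPC comes from a timing-permutation null: phases are
drawn from pseudo-random time points across the whole recording (so the
null preserves the phase distribution but destroys the lock to onsets)
and the pseudo-ITPC is recomputed, by default 10^4 times.

The lag scan couples two signals: for each candidate lag it computes the
mean resultant of the *phase difference* series (the standard two-signal
phase-locking value), records the lag maximizing it, and compares against
a null built from uniformly random phases of the same lengths.  A
positive lag means the target (peripheral) signal is delayed relative to
the EEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "icpc",
    "ITPCSeries",
    "itpc_timecourse",
    "ITPCNull",
    "itpc_null",
    "attach_null",
    "LagScanResult",
    "lag_scan",
    "lag_scan_null95",
]


def icpc(phases) -> float:
    """Resultant length |1/N sum exp(i theta_n)|, in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("ICPC of an empty phase vector")
    return float(np.abs(np.mean(np.exp(1j * phases))))


@dataclass
class ITPCSeries:
    """ITPC as a function of time from trial onset (1 Hz grid)."""

    t: np.ndarray
    itpc_t: np.ndarray
    n_trials: int
    null_quantiles: np.ndarray | None = None   # null 95% level per t
    p_t: np.ndarray | None = None


def itpc_timecourse(trial_phases, epoch_len: float = 30.0,
                    fs: float = 1.0) -> ITPCSeries:
    """ITPC at each time point of the first ``epoch_len`` s after onset.

    ``trial_phases``: sequence of per-trial phase series aligned to onset
    (or a trials x time array).  Trials shorter than the epoch are dropped
    with a warning; fewer than 2 surviving trials is an error.  The time
    axis has ``epoch_len * fs + 1`` points (t = 0 .. epoch_len inclusive).
    """
    n_t = int(round(epoch_len * fs)) + 1
    rows = []
    for k, tp in enumerate(trial_phases):
        tp = np.asarray(tp, dtype=float)
        if tp.size < n_t:
            warnings.warn(f"trial {k} shorter than the {epoch_len} s epoch; "
                          "dropped", stacklevel=2)
            continue
        rows.append(tp[:n_t])
    if len(rows) < 2:
        raise ValueError("fewer than 2 trials cover the epoch")
    ph = np.vstack(rows)
    vals = np.abs(np.mean(np.exp(1j * ph), axis=0))
    return ITPCSeries(t=np.arange(n_t) / fs, itpc_t=vals, n_trials=ph.shape[0])


@dataclass
class ITPCNull:
    """Permutation null for ITPC at a given trial count."""

    values: np.ndarray
    n_trials: int

    def p_value(self, observed) -> np.ndarray:
        """Empirical p with +1 correction: never exactly zero."""
        obs = np.atleast_1d(np.asarray(observed, dtype=float))
        n = self.values.size
        # counts of null >= each observed value, via sorted null
        srt = np.sort(self.values)
        ge = n - np.searchsorted(srt, obs, side="left")
        p = (1.0 + ge) / (1.0 + n)
        return p if np.ndim(observed) else float(p[0])

    def quantile(self, q: float = 0.95) -> float:
        return float(np.quantile(self.values, q))


def itpc_null(phase_pool, n_trials: int, n_perm: int = 10_000,
              seed=None) -> ITPCNull:
    """Timing-permutation null: pseudo-ITPC from random time points.

    Each replicate draws ``n_trials`` phases uniformly (with replacement
    across replicates) from ``phase_pool`` — all valid time points of the
    recording — and computes the resultant length.  Reproducible given
    ``seed`` (an int or a Generator).
    """
    pool = np.asarray(phase_pool, dtype=float).ravel()
    if pool.size < n_trials:
        raise ValueError("recording too short: pool smaller than n_trials")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: unstable null tail",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, pool.size, size=(n_perm, n_trials))
    vals = np.abs(np.mean(np.exp(1j * pool[draws]), axis=1))
    return ITPCNull(values=vals, n_trials=n_trials)


def attach_null(series: ITPCSeries, null: ITPCNull,
                q: float = 0.95) -> ITPCSeries:
    """Fill a time course's per-t p-values and null quantile in place."""
    if null.n_trials != series.n_trials:
        warnings.warn("null built for a different trial count", stacklevel=2)
    series.p_t = np.asarray(null.p_value(series.itpc_t))
    series.null_quantiles = np.full(series.t.size, null.quantile(q))
    return series


@dataclass
class LagScanResult:
    """Phase-locking of two signals as a function of the imposed lag."""

    lags: np.ndarray
    icpc_by_lag: np.ndarray
    best_lag: float
    best_icpc: float
    null95: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.null95 is None:
            return None
        return bool(self.best_icpc > self.null95)


def _plv_at_lags(z_eeg: np.ndarray, z_tgt: np.ndarray, lag_samps: np.ndarray,
                 min_overlap: int):
    """Mean resultant of exp(i(theta_eeg(t) - theta_tgt(t+lag))) per lag."""
    n = z_eeg.size
    vals = np.full(lag_samps.size, np.nan)
    for i, L in enumerate(lag_samps):
        if L >= 0:
            a, b = z_eeg[: n - L], z_tgt[L:]
        else:
            a, b = z_eeg[-L:], z_tgt[: n + L]
        if a.size < min_overlap:
            continue
        vals[i] = np.abs(np.mean(a * np.conj(b)))
    return vals


def lag_scan(eeg_phase, target_phase, lag_range: float = 60.0,
             lag_step: float = 1.0, fs: float = 1.0,
             min_overlap: int = 300, valid=None,
             null95: float | None = None, n_null: int = 1000,
             seed=None) -> LagScanResult:
    """Scan lags for maximal EEG-target phase locking.

    Positive lag = target delayed relative to the EEG, i.e., the statistic
    at lag L compares theta_eeg(t) with theta_target(t + L).  Lags whose
    overlap falls below ``min_overlap`` samples are dropped with a
    warning.  ``null95`` may be precomputed (:func:`lag_scan_null95`) and
    passed in; otherwise it is simulated here with ``n_null`` replicates.
    """
    th_e = np.asarray(eeg_phase, dtype=float)
    th_t = np.asarray(target_phase, dtype=float)
    if th_e.shape != th_t.shape:
        raise ValueError("phase series must share a time base")
    if valid is not None:
        v = np.asarray(valid, bool)
        th_e, th_t = th_e[v], th_t[v]
    n = th_e.size
    lag_samps = np.arange(-int(round(lag_range * fs)),
                          int(round(lag_range * fs)) + 1,
                          int(round(lag_step * fs)))
    vals = _plv_at_lags(np.exp(1j * th_e), np.exp(1j * th_t), lag_samps,
                        min_overlap)
    if np.isnan(vals).any():
        warnings.warn("some lags dropped: overlap below "
                      f"{min_overlap} samples", stacklevel=2)
    if np.isnan(vals).all():
        raise ValueError("no lag has sufficient overlap")
    best = int(np.nanargmax(vals))
    if null95 is None and n_null > 0:
        null95 = lag_scan_null95(n, lag_samps, fs=fs,
                                 min_overlap=min_overlap,
                                 n_null=n_null, seed=seed)
    return LagScanResult(
        lags=lag_samps / fs, icpc_by_lag=vals,
        best_lag=float(lag_samps[best] / fs), best_icpc=float(vals[best]),
        null95=null95,
    )


def lag_scan_null95(n_samples: int, lag_samps, fs: float = 1.0,
                    min_overlap: int = 300, n_null: int = 1000,
                    seed=None, q: float = 0.95) -> float:
    """95% level of best-lag phase locking for phase-randomized signals.

    Both series are replaced by i.i.d. uniform circular phases of the
    observed length; the best-lag statistic over the same lag grid is
    collected over ``n_null`` replicates and its ``q`` quantile returned.
    The null depends only on the series length and lag grid, so it can be
    computed once and shared across same-shaped scans.
    """
    rng = np.random.default_rng(seed)
    lag_samps = np.asarray(lag_samps, dtype=int)
    best = np.empty(n_null)
    block = max(1, int(2e6 // max(n_samples, 1)))
    done = 0
    while done < n_null:
        m = min(block, n_null - done)
        z1 = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(m, n_samples)))
        z2 = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(m, n_samples)))
        vals = np.full((m, lag_samps.size), -np.inf)
        for i, L in enumerate(lag_samps):
            if L >= 0:
                a, b = z1[:, : n_samples - L], z2[:, L:]
            else:
                a, b = z1[:, -L:], z2[:, : n_samples + L]
            if a.shape[1] < min_overlap:
                continue
            vals[:, i] = np.abs(np.mean(a * np.conj(b), axis=1))
        best[done:done + m] = vals.max(axis=1)
        done += m
    return float(np.quantile(best, q))
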
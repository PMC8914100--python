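"""Phase-amplitude coupling via phase binning and the d-prime statistic.

The coupling question: does the amplitude of a peripheral signal (skin
conductance, respiration) depend on the instantaneous phase of the EEG
infraslow oscillation?  The circle is split into ``n_bins`` equal bins
(default 8), the amplitude samples falling in each bin are summarized by
their median, and the bins with the largest and smallest median are
compared by

    d' = |mu_1 - mu_2| / ((sigma_1 + sigma_2) / 2)

together with a two-sample t-test between the two bins' amplitude
samples.  d' is a plain discriminability index: 0 means the extreme bins
are indistinguishable, ~1 means their means differ by about one average
standard deviation.  Note the test is anti-conservative under the null
because the compared bins are selected for extremity; the per-channel
p-values are reported as such, uncorrected, and callers needing a
calibrated null should use the permutation machinery in
:mod:`isapac.coherence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .signals import wrap_phase

__all__ = [
    "PhaseBinning",
    "PACResult",
    "SubjectPACSummary",
    "phase_bin_index",
    "dprime",
    "circular_mean",
    "circular_diff",
    "pac_channel",
    "subject_summary",
]


@dataclass(frozen=True)
class PhaseBinning:
    """Equal-width partition of the phase circle (-pi, pi].

    Bins are left-closed, right-open, except the last bin which closes at
    +pi so that the partition covers the circle exactly.
    """

    n_bins: int = 8

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(-np.pi, np.pi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def width(self) -> float:
        return 2.0 * np.pi / self.n_bins


def phase_bin_index(theta, binning: PhaseBinning = PhaseBinning()) -> np.ndarray:
    """Bin index in [0, n_bins) for each phase in (-pi, pi].

    Out-of-range phases raise; wrap first (:func:`~isapac.signals.wrap_phase`).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= -np.pi) or np.any(theta > np.pi):
        raise ValueError("phase outside (-pi, pi]; wrap before binning")
    idx = np.floor((theta + np.pi) / binning.width).astype(int)
    return np.minimum(idx, binning.n_bins - 1)


def dprime(x1, x2, ddof: int = 1) -> float:
    """Discriminability |mu1 - mu2| / ((sd1 + sd2)/2).

    Standard deviations are sample SDs (``ddof=1``) by convention here;
    pass ``ddof=0`` for the population variant.  If both SDs vanish the
    result is 0 for equal means and +inf (with a warning) otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("d-prime needs at least 2 samples per group")
    m1, m2 = x1.mean(), x2.mean()
    s1, s2 = x1.std(ddof=ddof), x2.std(ddof=ddof)
    if s1 + s2 == 0.0:
        if m1 == m2:
            return 0.0
        warnings.warn("zero variance in both groups with unequal means; "
                      "d-prime is infinite", stacklevel=2)
        return float("inf")
    return float(abs(m1 - m2) / ((s1 + s2) / 2.0))


def circular_mean(angles, weights=None) -> float:
    """Angle of the (weighted) resultant vector, in (-pi, pi].

    Raises when the resultant length is below 1e-9 (e.g., an antipodal
    pair), where the circular mean is undefined.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular mean of an empty set")
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    z = np.sum(w * np.exp(1j * angles)) / np.sum(w)
    if np.abs(z) <= 1e-9:
        raise ValueError("undefined circular mean: resultant length ~ 0")
    return float(wrap_phase(np.angle(z)))


def circular_diff(a, b):
    """Signed circular difference a - b, wrapped to (-pi, pi]."""
    return wrap_phase(np.asarray(a, float) - np.asarray(b, float))


@dataclass
class PACResult:
    """Coupling statistics for one EEG channel vs. one amplitude series."""

    bin_medians: np.ndarray
    bin_counts: np.ndarray
    max_bin: int
    min_bin: int
    phi_max: float
    phi_min: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    dprime: float
    p_value: float
    n1: int
    n2: int
    channel: str = ""

    @property
    def phase_diff(self) -> float:
        """Circular phi_max - phi_min; ~pi for sinusoidal coupling."""
        return float(circular_diff(self.phi_max, self.phi_min))


def pac_channel(eeg_phase, coupled_amp, binning: PhaseBinning = PhaseBinning(),
                alpha: float = 0.05, stat: str = "median",
                valid=None, equal_var: bool = False, ddof: int = 1,
                channel: str = "") -> PACResult:
    """Bin the coupled amplitude by EEG phase and test the extreme bins.

    Parameters
    ----------
    eeg_phase, coupled_amp : arrays, same length (1 Hz samples)
    stat : "median" (default, matches boxplot-style summaries) or "mean"
        Statistic that selects the max/min bins; d-prime and the t-test
        always use the raw amplitude samples of the selected bins.
    valid : optional boolean mask
        Samples excluded before binning (edge guards).
    equal_var : bool
        False (default) runs Welch's t-test; True the pooled-variance one.
    """
    theta = np.asarray(eeg_phase, dtype=float)
    amp = np.asarray(coupled_amp, dtype=float)
    if theta.shape != amp.shape:
        raise ValueError("phase and amplitude series must be aligned")
    if valid is not None:
        theta = theta[np.asarray(valid, bool)]
        amp = amp[np.asarray(valid, bool)]
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")

    idx = phase_bin_index(theta, binning)
    counts = np.bincount(idx, minlength=binning.n_bins)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(
            f"empty phase bin(s) {empty.tolist()} "
            f"(centers {np.round(binning.centers[empty], 3).tolist()} rad): "
            "insufficient data to compare bins"
        )
    reducer = np.median if stat == "median" else np.mean
    summaries = np.array([reducer(amp[idx == b])
                          for b in range(binning.n_bins)])
    max_bin = int(np.argmax(summaries))
    min_bin = int(np.argmin(summaries))
    x1 = amp[idx == max_bin]
    x2 = amp[idx == min_bin]
    d = dprime(x1, x2, ddof=ddof) if max_bin != min_bin else 0.0
    if max_bin != min_bin:
        t = _stats.ttest_ind(x1, x2, equal_var=equal_var)
        p = float(t.pvalue)
    else:
        p = 1.0
    return PACResult(
        bin_medians=summaries, bin_counts=counts,
        max_bin=max_bin, min_bin=min_bin,
        phi_max=float(binning.centers[max_bin]),
        phi_min=float(binning.centers[min_bin]),
        mu1=float(x1.mean()), sigma1=float(x1.std(ddof=ddof)),
        mu2=float(x2.mean()), sigma2=float(x2.std(ddof=ddof)),
        dprime=d, p_value=p, n1=int(x1.size), n2=int(x2.size),
        channel=channel,
    )


@dataclass
class SubjectPACSummary:
    """Channel-aggregated coupling summary for one subject."""

    sig_channel_ratio: float
    mean_dprime: float
    mean_phi_max: float
    phase_diff: np.ndarray
    n_channels: int


def subject_summary(results: list[PACResult], alpha: float = 0.05,
                    on_undefined: str = "raise") -> SubjectPACSummary:
    """Aggregate per-channel PAC results for a subject.

    ``sig_channel_ratio`` is the fraction of channels with p < alpha
    (uncorrected, one test per channel); ``mean_phi_max`` is the circular
    mean of the per-channel preferred phases.  When that mean is undefined
    (antipodal resultant ~ 0, typical for uncoupled data with quantized
    bin centres), ``on_undefined`` picks the behaviour: "raise" (default)
    or "nan" (warn and record NaN).
    """
    if not results:
        raise ValueError("no channel results to summarize")
    p = np.array([r.p_value for r in results])
    d = np.array([r.dprime for r in results])
    phi = np.array([r.phi_max for r in results])
    try:
        mean_phi = circular_mean(phi)
    except ValueError:
        if on_undefined != "nan":
            raise
        warnings.warn("circular mean of preferred phases undefined "
                      "(resultant ~ 0); recording NaN", stacklevel=2)
        mean_phi = float("nan")
    return SubjectPACSummary(
        sig_channel_ratio=float(np.mean(p < alpha)),
        mean_dprime=float(np.mean(d)),
        mean_phi_max=mean_phi,
        phase_diff=np.array([r.phase_diff for r in results]),
        n_channels=len(results),
    )
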
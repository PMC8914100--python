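"""Band-limited phase/amplitude extraction for infraslow activity (ISA).

The processing chain mirrors the standard ISA workflow: zero-phase bandpass
(0.01-0.1 Hz) or highpass (0.01 Hz) filtering at the native sampling rate,
Hilbert transform to obtain the analytic phase and amplitude envelope,
instantaneous frequency as the derivative of the unwrapped phase, and only
then decimation to the 1 Hz analysis rate.  The order matters: extracting
the analytic signal from an already-decimated series distorts phase near
the band edges, so :func:`analytic` is always applied at the native rate.

Filters are second-order Butterworth sections applied forward-backward
(zero phase, effective order 4).  At a 0.01 Hz edge the transient extends
over tens of seconds, so every analytic series carries an *edge guard*: a
configurable stretch at each end flagged unreliable and excluded from
statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.fft import next_fast_len

__all__ = [
    "AnalyticSeries",
    "Spectrum",
    "wrap_phase",
    "bandpass_isa",
    "highpass",
    "analytic",
    "instantaneous_frequency",
    "downsample",
    "magnitude_spectrum",
    "spectral_slope",
]

ISA_BAND = (0.01, 0.1)


def wrap_phase(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the half-open interval (-pi, pi].

    -pi itself maps to +pi, so the output range is exactly (-pi, pi].
    """
    w = np.mod(theta, 2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    # mod can return values in [0, 2pi); 0 stays 0, pi stays pi
    if np.ndim(theta) == 0:
        return float(w)
    return w


@dataclass
class AnalyticSeries:
    """Instantaneous phase and amplitude of a band-limited signal.

    Attributes
    ----------
    phase : ndarray
        Instantaneous phase in radians, wrapped to (-pi, pi].
    amplitude : ndarray
        Nonnegative envelope (modulus of the analytic signal).
    fs : float
        Sampling rate in Hz.
    source_band : tuple of float
        (low, high) edges in Hz of the filter applied before the Hilbert
        transform; for highpass-only input the high edge is the Nyquist.
    edge_guard_s : float
        Seconds at each end flagged unreliable (filter + Hilbert edge
        transients).
    """

    phase: np.ndarray
    amplitude: np.ndarray
    fs: float
    source_band: tuple[float, float] = ISA_BAND
    edge_guard_s: float = 100.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude envelope must be nonnegative")

    def __len__(self) -> int:
        return self.phase.size

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask: True where the sample is outside the edge guard."""
        n = len(self)
        guard = int(round(self.edge_guard_s * self.fs))
        mask = np.ones(n, dtype=bool)
        if guard > 0:
            mask[: min(guard, n)] = False
            mask[max(n - guard, 0):] = False
        return mask

    def downsample(self, fs_out: float = 1.0) -> "AnalyticSeries":
        """Decimate phase and amplitude to ``fs_out`` (integer ratio)."""
        return AnalyticSeries(
            phase=downsample(self.phase, self.fs, fs_out),
            amplitude=downsample(self.amplitude, self.fs, fs_out),
            fs=fs_out,
            source_band=self.source_band,
            edge_guard_s=self.edge_guard_s,
        )


@dataclass
class Spectrum:
    """Magnitude spectrum: |FFT| at nonnegative frequencies."""

    freqs: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.freqs.shape != self.magnitude.shape:
            raise ValueError("freqs and magnitude must have equal length")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValueError("freqs must be nonnegative and ascending")


def _design_sos(fs: float, btype: str, cutoff, order: int) -> np.ndarray:
    return _sig.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def _min_length(fs: float, low: float, sos: np.ndarray) -> int:
    # three time constants of the low edge, and sosfiltfilt's padding need
    tc = int(np.ceil(3.0 * fs / (2.0 * np.pi * low)))
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    return max(tc, padlen + 1)


def _zero_phase(x: np.ndarray, fs: float, btype: str, cutoff, low: float,
                order: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sos = _design_sos(fs, btype, cutoff, order)
    nmin = _min_length(fs, low, sos)
    if x.shape[-1] < nmin:
        raise ValueError(
            f"series too short for stable {btype} filtering with a "
            f"{low} Hz edge at fs={fs} Hz: need at least {nmin} samples "
            f"({nmin / fs:.1f} s), got {x.shape[-1]}"
        )
    return _sig.sosfiltfilt(sos, x, axis=-1)


def bandpass_isa(x: np.ndarray, fs: float, low: float = 0.01,
                 high: float = 0.1, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth bandpass, defaulting to the ISA band.

    ``order`` is per pass; forward-backward application doubles the
    effective order and cancels phase distortion.  Requires
    ``fs > 2 * high``.
    """
    if fs <= 2.0 * high:
        raise ValueError(f"fs={fs} must exceed twice the high edge {high}")
    return _zero_phase(x, fs, "bandpass", (low, high), low, order)


def highpass(x: np.ndarray, fs: float, cutoff: float = 0.01,
             order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth highpass; removes drifts below ``cutoff``."""
    return _zero_phase(x, fs, "highpass", cutoff, cutoff, order)


def analytic(x: np.ndarray, fs: float,
             source_band: tuple[float, float] = ISA_BAND,
             edge_guard_s: float = 100.0) -> AnalyticSeries:
    """Analytic phase and envelope of an already band-limited series.

    The input must have been filtered to ``source_band`` beforehand; the
    Hilbert transform of a broadband signal has no meaningful single
    phase.  The first and last ``edge_guard_s`` seconds are flagged
    unreliable via :attr:`AnalyticSeries.valid`.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.any(x):
        raise ValueError("analytic phase of an all-zero series is undefined")
    n = x.shape[-1]
    z = _sig.hilbert(x, N=next_fast_len(n))[..., :n]
    return AnalyticSeries(
        phase=wrap_phase(np.angle(z)),
        amplitude=np.abs(z),
        fs=fs,
        source_band=source_band,
        edge_guard_s=edge_guard_s,
    )


def instantaneous_frequency(a: AnalyticSeries) -> np.ndarray:
    """Instantaneous frequency in Hz: d(theta)/dt / 2pi.

    The phase is unwrapped before differentiation; interior samples use
    central differences, the endpoints one-sided differences.
    """
    if len(a) < 2:
        raise ValueError("need at least 2 samples to differentiate phase")
    theta = np.unwrap(a.phase)
    return np.gradient(theta, 1.0 / a.fs) / (2.0 * np.pi)


def downsample(x: np.ndarray, fs_in: float, fs_out: float = 1.0) -> np.ndarray:
    """Decimate a band-limited series by plain sample-picking.

    Valid only when the content is already confined well below the output
    Nyquist (0.5 Hz at the default 1 Hz output vs. the 0.1 Hz ISA edge),
    so no extra anti-alias filter is applied.  The kept samples are
    x[0], x[ratio], x[2*ratio], ... so output sample k sits at time
    k/fs_out on the source timeline.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    return np.asarray(x)[..., :: int(round(ratio))]


def magnitude_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """Absolute FFT coefficients at nonnegative frequencies."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute a spectrum of an empty series")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return Spectrum(freqs=freqs, magnitude=mag)


def spectral_slope(spec: Spectrum, band: tuple[float, float] = ISA_BAND) -> float:
    """Least-squares slope of log10(magnitude) vs log10(frequency) in ``band``."""
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs <= hi) & (spec.magnitude > 0)
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 spectral points in band {band}")
    return float(np.polyfit(np.log10(spec.freqs[sel]),
                            np.log10(spec.magnitude[sel]), 1)[0])
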
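"""Synthetic multichannel sessions with known infraslow coupling.

The generator produces recordings with the statistical structure the
analysis assumes, so every pipeline stage can be validated against ground
truth without real data:

* a 1/f (pink) background in every channel,
* a quasi-periodic infraslow oscillation around ``f0`` (default 0.05 Hz)
  whose instantaneous frequency performs a reflected random walk inside
  the 0.01-0.1 Hz band, shared across EEG channels up to a per-channel
  phase offset,
* a skin-conductance (GSR) channel whose *fluctuation magnitude* is
  modulated by the infraslow phase: the signal is an in-band carrier
  (default 0.3 Hz, a plausible electrodermal fluctuation rate) whose
  envelope is ``1 + depth * m * cos(phi(t - lag) - phi_pref)``, riding on
  a positive conductance baseline.  The Hilbert envelope of the
  highpass-filtered channel therefore tracks the infraslow phase, and the
  infraslow-band phase of that envelope carries the configured lag —
  which is what the coupling and lag-scan analyses measure,
* a respiration channel built the same way (carrier 0.25 Hz, roughly 15
  breaths/min) with its own, typically longer, lag and weaker depth,
* trial onsets with von-Mises partial phase reset of the master
  oscillator, producing elevated inter-trial phase coherence at onset
  that decays as frequency jitter decorrelates the trials.

All randomness flows from ``SyntheticConfig.seed`` through independent
child generators, so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .recording import Recording, write_edf, write_events_tsv

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "gen_pink_noise",
    "gen_isa_phase",
    "gen_session",
    "write_session",
]

ISA_LO, ISA_HI = 0.01, 0.1


@dataclass
class SyntheticConfig:
    """Full parameterization of the generative model.

    Units: seconds, Hz, radians; amplitudes in the recording's physical
    units (uV-scale for EEG, uS-scale for GSR).  ``m`` is the coupling
    depth as a fraction of the peripheral envelope (0 = no coupling,
    1 = full modulation); ``resp_m`` defaults to half of ``m`` so skin
    conductance couples more strongly than respiration.
    """

    duration: float = 7200.0
    fs: float = 256.0
    n_eeg: int = 64
    f0: float = 0.05
    freq_jitter_sd: float = 0.005     # Hz per sqrt(s) random-walk scale
    isa_amp: float = 10.0             # uV, infraslow oscillation
    pink_slope: float = -1.0          # PSD exponent of the background
    pink_amp: float = 5.0             # uV, background sd
    phi_pref: float = 0.0             # preferred coupling phase, rad
    m: float = 1.0                    # GSR coupling depth in [0, 1]
    resp_m: float | None = None       # respiration depth; default m / 2
    gsr_noise_sd: float = 0.05        # uS, additive white noise
    gsr_lag: float = 0.0              # s, GSR delayed vs EEG
    resp_lag: float = 10.0            # s
    gsr_carrier_f: float = 0.3        # Hz, electrodermal fluctuation rate
    resp_carrier_f: float = 0.25      # Hz, ~15 breaths per minute
    gsr_env_base: float = 1.0         # uS, carrier envelope baseline
    gsr_baseline: float = 10.0        # uS, tonic conductance level
    depth_frac: float = 0.9           # max envelope modulation fraction
    n_trials: int = 41
    trial_len_range: tuple[float, float] = (30.0, 90.0)
    iti_range: tuple[float, float] = (15.0, 45.0)
    reset_kappa: float = 0.0          # von-Mises reset concentration
    reset_phase: float = 0.0          # rad, phase drawn toward at onsets
    freq_reversion_tau: float = 60.0  # s, mean-reversion timescale of freq
    channel_phase_sd: float = 0.3     # rad, inter-channel phase scatter
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not 0.0 <= self.m <= 1.0:
            problems.append(f"m={self.m} not in [0, 1]")
        if self.resp_m is not None and not 0.0 <= self.resp_m <= 1.0:
            problems.append(f"resp_m={self.resp_m} not in [0, 1]")
        if self.duration < 10.0 / self.f0:
            problems.append(f"duration={self.duration} < 10 cycles of f0")
        if not 0.0 < self.f0 < self.fs / 2:
            problems.append(f"f0={self.f0} outside (0, fs/2)")
        for name in ("isa_amp", "pink_amp", "gsr_noise_sd", "gsr_env_base",
                     "gsr_baseline", "freq_jitter_sd", "channel_phase_sd",
                     "reset_kappa"):
            if getattr(self, name) < 0:
                problems.append(f"{name}={getattr(self, name)} < 0")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    phi: np.ndarray            # master infraslow phase at cfg.fs, wrapped
    freq: np.ndarray           # instantaneous frequency of phi, Hz
    onsets: np.ndarray         # s
    trial_durations: np.ndarray
    channel_offsets: np.ndarray
    config: SyntheticConfig


def gen_pink_noise(n: int, fs: float, slope: float = -1.0,
                   seed=None) -> np.ndarray:
    """Fourier-synthesized noise with power spectral density ~ f^slope.

    The FFT magnitude is shaped as f^(slope/2) (magnitude slope is half
    the PSD slope) with random phases; the DC term is zero and the output
    is normalized to unit standard deviation.
    """
    if n < 16:
        raise ValueError(f"need n >= 16 samples, got {n}")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(freqs.size)
    shape[1:] = freqs[1:] ** (slope / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = shape * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_onsets(cfg: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    onsets, durations = [], []
    t = rng.uniform(*cfg.iti_range) + 120.0   # stay clear of the edge guard
    for _ in range(cfg.n_trials):
        length = rng.uniform(*cfg.trial_len_range)
        if t + length + 120.0 > cfg.duration:
            break
        onsets.append(t)
        durations.append(length)
        t += length + rng.uniform(*cfg.iti_range)
    return np.asarray(onsets), np.asarray(durations)


def gen_isa_phase(duration: float, fs: float, f0: float = 0.05,
                  freq_jitter_sd: float = 0.005, seed=None,
                  onsets=None, reset_kappa: float = 0.0,
                  reset_phase: float = 0.0,
                  phi0: float | None = None,
                  freq_reversion_tau: float = 60.0):
    """Master infraslow phase: mean-reverting-random-walk frequency,
    optional von-Mises phase reset at trial onsets.

    Returns (wrapped phase, instantaneous frequency), both at ``fs``.
    The instantaneous frequency performs a random walk around ``f0``
    (per-second innovation sd ``freq_jitter_sd``) with mean reversion on
    the ``freq_reversion_tau`` timescale — without reversion the walk
    would mix toward the band centre and forget ``f0`` — and reflects at
    the 0.01 / 0.1 Hz band edges.  At each onset, if ``reset_kappa > 0``,
    the phase jumps to a von-Mises draw centred on ``reset_phase``.
    """
    if not 0.0 < f0 < fs / 2:
        raise ValueError(f"f0={f0} outside (0, fs/2)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    if freq_jitter_sd == 0.0:
        freq = np.full(n, f0)
    else:
        # AR(1) discretization of the mean-reverting walk
        a = 1.0 - dt / freq_reversion_tau
        innov = rng.normal(0.0, freq_jitter_sd * np.sqrt(dt), size=n)
        from scipy.signal import lfilter
        dev = lfilter([1.0], [1.0, -a], innov)
        freq = f0 + dev
    # reflect into [ISA_LO, ISA_HI]
    span = ISA_HI - ISA_LO
    freq = ISA_LO + span - np.abs(np.mod(freq - ISA_LO, 2 * span) - span)
    phi = np.cumsum(2.0 * np.pi * freq / fs)
    phi += (rng.uniform(-np.pi, np.pi) if phi0 is None else phi0) - phi[0]
    if onsets is not None and reset_kappa > 0:
        for on in np.asarray(onsets, dtype=float):
            i = int(round(on * fs))
            if not 0 <= i < n:
                continue
            target = rng.vonmises(reset_phase, reset_kappa)
            phi[i:] += target - phi[i]
    from .signals import wrap_phase
    return wrap_phase(phi), freq


def _delayed(phi: np.ndarray, lag_s: float, fs: float) -> np.ndarray:
    """phi(t - lag): the returned series at time t shows the master phase
    lag seconds earlier (edge-padded)."""
    k = int(round(lag_s * fs))
    if k == 0:
        return phi
    out = np.empty_like(phi)
    if k > 0:
        out[k:] = phi[:-k]
        out[:k] = phi[0]
    else:
        out[:k] = phi[-k:]
        out[k:] = phi[-1]
    return out


def _peripheral_channel(phi: np.ndarray, cfg: SyntheticConfig, depth: float,
                        lag: float, carrier_f: float, baseline: float,
                        rng) -> np.ndarray:
    """Carrier with infraslow-phase-modulated envelope + baseline + noise."""
    n = phi.size
    # quasi-periodic carrier with mild frequency jitter of its own
    cf = carrier_f * (1.0 + 0.05 * np.cumsum(
        rng.normal(0, 1 / np.sqrt(cfg.fs), n)) / np.sqrt(max(n / cfg.fs, 1)))
    psi = np.cumsum(2 * np.pi * np.clip(cf, 0.05, 0.45 * min(cfg.fs / 2, 1.0))
                    / cfg.fs) + rng.uniform(0, 2 * np.pi)
    env = cfg.gsr_env_base * (
        1.0 + cfg.depth_frac * depth
        * np.cos(_delayed(phi, lag, cfg.fs) - cfg.phi_pref))
    x = baseline + env * np.cos(psi)
    if cfg.gsr_noise_sd > 0:
        x = x + rng.normal(0, cfg.gsr_noise_sd, n)
    return x


def gen_session(cfg: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Generate one full synthetic session (EEG + GSR + RESP channels)."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=6)
    rng_onset = np.random.default_rng(seeds[0])
    onsets, durations = _draw_onsets(cfg, rng_onset)

    phi, freq = gen_isa_phase(cfg.duration, cfg.fs, cfg.f0,
                              cfg.freq_jitter_sd, seed=seeds[1],
                              onsets=onsets, reset_kappa=cfg.reset_kappa,
                              reset_phase=cfg.reset_phase,
                              freq_reversion_tau=cfg.freq_reversion_tau)
    n = phi.size
    rng_ch = np.random.default_rng(seeds[2])
    offsets = rng_ch.normal(0.0, cfg.channel_phase_sd, size=cfg.n_eeg)

    unwrapped = np.unwrap(phi)
    data = np.empty((cfg.n_eeg + 2, n))
    labels, modality = [], []
    for c in range(cfg.n_eeg):
        pink = gen_pink_noise(n, cfg.fs, cfg.pink_slope,
                              seed=rng_ch.integers(0, 2**31 - 1))
        data[c] = (cfg.pink_amp * pink
                   + cfg.isa_amp * np.cos(unwrapped + offsets[c]))
        labels.append(f"EEG{c + 1:03d}")
        modality.append("EEG")

    resp_m = cfg.m / 2.0 if cfg.resp_m is None else cfg.resp_m
    data[cfg.n_eeg] = _peripheral_channel(
        unwrapped, cfg, cfg.m, cfg.gsr_lag, cfg.gsr_carrier_f,
        cfg.gsr_baseline, np.random.default_rng(seeds[3]))
    labels.append("GSR")
    modality.append("GSR")
    data[cfg.n_eeg + 1] = _peripheral_channel(
        unwrapped, cfg, resp_m, cfg.resp_lag, cfg.resp_carrier_f,
        0.0, np.random.default_rng(seeds[4]))
    labels.append("Resp")
    modality.append("RESP")

    rec = Recording(data=data, fs=cfg.fs, channel_labels=labels,
                    modality=modality, trial_onsets=onsets,
                    subject_id=f"synth-{cfg.seed:04d}")
    truth = GroundTruth(phi=phi, freq=freq, onsets=onsets,
                        trial_durations=durations,
                        channel_offsets=offsets, config=cfg)
    return rec, truth


def write_session(rec: Recording, out_dir, stem: str | None = None,
                  trial_durations=None) -> dict[str, str]:
    """Write a session as EDF + BIDS-style events TSV; returns the paths."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.subject_id or "session"
    dims = ["uV" if m == "EEG" else ("uS" if m == "GSR" else "a.u.")
            for m in rec.modality]
    edf = out_dir / f"{stem}_eeg.edf"
    write_edf(edf, rec.data, rec.fs, rec.channel_labels, physical_dims=dims)
    events = out_dir / f"{stem}_events.tsv"
    write_events_tsv(events, rec.trial_onsets, trial_durations)
    return {"edf": str(edf), "events": str(events)}
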
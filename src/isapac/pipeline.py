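"""End-to-end preprocessing and per-subject analysis drivers.

`preprocess_recording` turns a raw multichannel recording into 1 Hz
phase/amplitude series: EEG channels are bandpassed to the infraslow band
(0.01-0.1 Hz) and Hilbert-transformed at the native rate, instantaneous
frequency is computed from the unwrapped phase, and only then is
everything decimated to 1 Hz.  Peripheral channels (GSR, respiration) are
highpass-filtered at 0.01 Hz; their "amplitude" is by default the Hilbert
envelope (the filtered signed value is available via
``peripheral_amp="filtered"``), and for lag/coherence analyses their
infraslow-band phase is extracted from that envelope.

The per-subject drivers run the coupling analysis (PAC per EEG channel
against the GSR amplitude), the inter-trial coherence time courses, and
the lag scans, returning tidy DataFrames ready for TSV export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import signals as sg
from .coherence import ITPCSeries, itpc_timecourse, lag_scan
from .groups import extract_epochs
from .pac import PACResult, PhaseBinning, pac_channel, subject_summary
from .recording import Recording

__all__ = ["PreprocessedSession", "preprocess_recording",
           "run_subject_pac", "eeg_epoch_phases", "subject_itpc"]


@dataclass
class PreprocessedSession:
    """1 Hz phase/amplitude series for one recording.

    EEG arrays are channels x time; peripheral series are 1-D.  ``valid``
    marks samples outside the filter edge guard.
    """

    fs: float
    eeg_labels: list[str]
    eeg_phase: np.ndarray
    eeg_amp: np.ndarray
    eeg_freq: np.ndarray
    gsr_amp: np.ndarray | None
    gsr_phase: np.ndarray | None
    resp_amp: np.ndarray | None
    resp_phase: np.ndarray | None
    valid: np.ndarray
    trial_onsets: np.ndarray
    subject_id: str
    group_label: str | None
    params: dict = field(default_factory=dict)

    @property
    def n_eeg(self) -> int:
        return self.eeg_phase.shape[0]

    def to_tsv(self, path) -> None:
        """Long-format dump: time, channel, phase, amplitude (+ sidecar)."""
        t = np.arange(self.eeg_phase.shape[1]) / self.fs
        frames = []
        for i, lab in enumerate(self.eeg_labels):
            frames.append(pd.DataFrame({
                "time": t, "channel": lab,
                "phase": self.eeg_phase[i], "amplitude": self.eeg_amp[i]}))
        for name, ph, am in (("GSR", self.gsr_phase, self.gsr_amp),
                             ("RESP", self.resp_phase, self.resp_amp)):
            if am is not None:
                frames.append(pd.DataFrame({
                    "time": t, "channel": name, "phase": ph,
                    "amplitude": am}))
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t",
                                                    index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"subject_id": self.subject_id, "fs": self.fs,
             "trial_onsets": self.trial_onsets.tolist(), **self.params},
            indent=2))


def _peripheral(x, fs, out_fs, hp_cutoff, band, edge_guard_s, mode):
    """Highpass + Hilbert a peripheral channel; return (amp, isa_phase)
    at the analysis rate."""
    hp = sg.highpass(x, fs, cutoff=hp_cutoff)
    env = sg.analytic(hp, fs, source_band=(hp_cutoff, fs / 2),
                      edge_guard_s=edge_guard_s).amplitude
    amp_full = hp if mode == "filtered" else env
    # infraslow-band phase of the amplitude fluctuation, for lag scans
    iso = sg.bandpass_isa(env, fs, *band)
    ph = sg.analytic(iso, fs, source_band=band,
                     edge_guard_s=edge_guard_s).phase
    return (sg.downsample(amp_full, fs, out_fs),
            sg.downsample(ph, fs, out_fs))


def preprocess_recording(rec: Recording,
                         band: tuple[float, float] = (0.01, 0.1),
                         out_fs: float = 1.0,
                         hp_cutoff: float = 0.01,
                         edge_guard_s: float = 100.0,
                         peripheral_amp: str = "envelope",
                         ) -> PreprocessedSession:
    """Filter, Hilbert-transform and decimate a recording to 1 Hz."""
    if peripheral_amp not in ("envelope", "filtered"):
        raise ValueError("peripheral_amp must be 'envelope' or 'filtered'")
    eeg_idx = rec.channels("EEG")
    if eeg_idx.size == 0:
        raise ValueError("recording has no EEG channels")

    bp = sg.bandpass_isa(rec.data[eeg_idx], rec.fs, *band)
    phases, amps, freqs = [], [], []
    for row in bp:
        a = sg.analytic(row, rec.fs, source_band=band,
                        edge_guard_s=edge_guard_s)
        phases.append(sg.downsample(a.phase, rec.fs, out_fs))
        amps.append(sg.downsample(a.amplitude, rec.fs, out_fs))
        freqs.append(sg.downsample(sg.instantaneous_frequency(a),
                                   rec.fs, out_fs))
    eeg_phase = np.vstack(phases)

    gsr_amp = gsr_phase = resp_amp = resp_phase = None
    for mod in ("GSR", "RESP"):
        idx = rec.channels(mod)
        if idx.size == 0:
            continue
        amp, ph = _peripheral(rec.data[idx[0]], rec.fs, out_fs, hp_cutoff,
                              band, edge_guard_s, peripheral_amp)
        if mod == "GSR":
            gsr_amp, gsr_phase = amp, ph
        else:
            resp_amp, resp_phase = amp, ph

    n_out = eeg_phase.shape[1]
    guard = int(round(edge_guard_s * out_fs))
    valid = np.ones(n_out, dtype=bool)
    if guard > 0:
        valid[:guard] = False
        valid[n_out - guard:] = False

    return PreprocessedSession(
        fs=out_fs, eeg_labels=[rec.channel_labels[i] for i in eeg_idx],
        eeg_phase=eeg_phase, eeg_amp=np.vstack(amps),
        eeg_freq=np.vstack(freqs),
        gsr_amp=gsr_amp, gsr_phase=gsr_phase,
        resp_amp=resp_amp, resp_phase=resp_phase,
        valid=valid, trial_onsets=rec.trial_onsets,
        subject_id=rec.subject_id, group_label=rec.group_label,
        params={"band": list(band), "out_fs": out_fs,
                "hp_cutoff": hp_cutoff, "edge_guard_s": edge_guard_s,
                "peripheral_amp": peripheral_amp,
                "source_fs": rec.fs},
    )


def run_subject_pac(pre: PreprocessedSession, target: str = "GSR",
                    binning: PhaseBinning = PhaseBinning(),
                    alpha: float = 0.05, stat: str = "median"):
    """PAC of every EEG channel against the peripheral amplitude.

    Returns (per-channel results, subject summary, tidy DataFrame).
    """
    amp = pre.gsr_amp if target == "GSR" else pre.resp_amp
    if amp is None:
        raise ValueError(f"session has no {target} channel")
    results = [
        pac_channel(pre.eeg_phase[i], amp, binning=binning, alpha=alpha,
                    stat=stat, valid=pre.valid, channel=lab)
        for i, lab in enumerate(pre.eeg_labels)
    ]
    summary = subject_summary(results, alpha=alpha, on_undefined="nan")
    df = pd.DataFrame([{
        "subject": pre.subject_id, "channel": r.channel,
        "phi_max": r.phi_max, "phi_min": r.phi_min,
        "dprime": r.dprime, "p": r.p_value, "n1": r.n1, "n2": r.n2,
    } for r in results])
    return results, summary, df


def eeg_epoch_phases(pre: PreprocessedSession, channel: int,
                     epoch_len: float = 30.0) -> np.ndarray:
    """Trials x time phase matrix for one EEG channel."""
    ep = extract_epochs(pre.eeg_phase[channel], pre.trial_onsets,
                        epoch_len=epoch_len, fs=pre.fs)
    return ep.values


def subject_itpc(pre: PreprocessedSession, channel: int,
                 epoch_len: float = 30.0) -> ITPCSeries:
    """ITPC time course for one EEG channel of one subject."""
    return itpc_timecourse(eeg_epoch_phases(pre, channel, epoch_len),
                           epoch_len=epoch_len, fs=pre.fs)
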
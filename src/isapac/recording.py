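"""Multichannel recording container and EDF/BDF + events-table I/O.

Reading goes through MNE's native EDF/BDF readers and a BIDS-style events
TSV (columns ``onset`` and ``duration``, in seconds).  Writing uses a
minimal 16-bit EDF writer implemented here, since no EDF export library is
part of this package's dependency set; the writer emits one data record
per second with per-channel physical scaling, which MNE reads back within
the 16-bit quantization step.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ModalityConfigError",
    "DEFAULT_MODALITY_PATTERNS",
    "read_recording",
    "read_events_tsv",
    "write_events_tsv",
    "write_edf",
]

MODALITIES = ("EEG", "GSR", "RESP")

#: Tried in order; the first matching pattern tags the channel.  The EEG
#: catch-all comes last so unlabeled scalp channels default to EEG.
DEFAULT_MODALITY_PATTERNS: tuple[tuple[str, str], ...] = (
    ("GSR", r"(?i)gsr|eda|skin|scr\b"),
    ("RESP", r"(?i)resp|breath|thorax|belt"),
    ("EEG", r".*"),
)


class ModalityConfigError(ValueError):
    """A channel label matched none of the configured modality patterns."""


@dataclass
class Recording:
    """A multichannel physiological recording.

    ``data`` is channels x samples in the signal's physical units (uV for
    EEG, uS for skin conductance).  ``trial_onsets`` are seconds from the
    start of the recording.  Non-finite samples are rejected at
    construction: silent interpolation would bias every statistic built on
    top.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    modality: list[str]
    trial_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.modality) != n_ch:
            raise ValueError("labels/modality length must match channel count")
        bad = [m for m in self.modality if m not in MODALITIES]
        if bad:
            raise ValueError(f"unknown modality tags: {sorted(set(bad))}")
        finite = np.isfinite(self.data).all(axis=1)
        if not finite.all():
            names = [self.channel_labels[i] for i in np.flatnonzero(~finite)]
            raise ValueError(f"non-finite samples in channel(s): {names}")
        if self.trial_onsets.size:
            if np.any(np.diff(self.trial_onsets) <= 0):
                raise ValueError("trial_onsets must be strictly increasing")
            if self.trial_onsets[0] < 0 or self.trial_onsets[-1] > self.duration:
                raise ValueError("trial_onsets must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels(self, modality: str) -> np.ndarray:
        """Indices of channels carrying the given modality tag."""
        return np.flatnonzero([m == modality for m in self.modality])


def tag_modalities(labels: list[str],
                   patterns=DEFAULT_MODALITY_PATTERNS) -> list[str]:
    """Map channel labels to modality tags via ordered regex patterns."""
    out = []
    for lab in labels:
        for modality, pat in patterns:
            if re.search(pat, lab):
                out.append(modality)
                break
        else:
            raise ModalityConfigError(
                f"channel label {lab!r} matches no modality pattern; "
                f"extend the pattern map"
            )
    return out


def read_events_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a BIDS-style events table; returns (onsets, durations) in s."""
    df = pd.read_csv(path, sep="\t")
    if "onset" not in df.columns:
        raise ValueError(f"events table {path} lacks an 'onset' column")
    onsets = df["onset"].to_numpy(dtype=float)
    durations = (df["duration"].to_numpy(dtype=float)
                 if "duration" in df.columns else np.full(onsets.size, np.nan))
    return onsets, durations


def write_events_tsv(path, onsets, durations=None) -> None:
    onsets = np.asarray(onsets, dtype=float)
    if durations is None:
        durations = np.full(onsets.size, 30.0)
    pd.DataFrame({"onset": onsets, "duration": durations}).to_csv(
        path, sep="\t", index=False)


def _find_events_path(rec_path: Path) -> Path | None:
    stem = rec_path.stem
    candidates = [rec_path.with_suffix(".tsv")]
    if stem.endswith("_eeg"):
        candidates.append(rec_path.with_name(stem[:-4] + "_events.tsv"))
    candidates.append(rec_path.with_name(stem + "_events.tsv"))
    for c in candidates:
        if c.exists():
            return c
    return None


def read_recording(path, events_path=None,
                   modality_patterns=DEFAULT_MODALITY_PATTERNS,
                   subject_id: str | None = None,
                   group_label: str | None = None) -> Recording:
    """Read an EDF/BDF recording plus its companion events table.

    ``events_path`` defaults to the BIDS sibling (``*_events.tsv``); if no
    events table is found the recording is returned with empty onsets and
    a warning, since several analyses (PAC, lag scans) need none.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        elif suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported recording format: {suffix}")
    except ValueError:
        raise
    except Exception as exc:  # mne raises various types for corrupt files
        raise ValueError(f"could not parse {path} as EDF/BDF: {exc}") from exc

    labels = list(raw.ch_names)
    data = raw.get_data()
    # MNE rescales EEG-typed channels to volts; undo any uniform scaling by
    # using the file's physical values directly via the orig units map.
    units = getattr(raw, "_orig_units", {}) or {}
    for i, lab in enumerate(labels):
        if units.get(lab) in ("µV", "uV"):
            data[i] *= 1e6

    if events_path is None:
        events_path = _find_events_path(path)
    if events_path is None:
        warnings.warn(f"no events table found next to {path.name}; "
                      "trial onsets left empty", stacklevel=2)
        onsets = np.empty(0)
    else:
        onsets, _ = read_events_tsv(events_path)

    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        modality=tag_modalities(labels, modality_patterns),
        trial_onsets=onsets,
        subject_id=subject_id or path.stem,
        group_label=group_label,
    )


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, one data record per second)

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, fs: float, labels: list[str],
              physical_dims: list[str] | None = None) -> None:
    """Write channels x samples to a 16-bit EDF file.

    ``fs`` must be a positive integer and the duration a whole number of
    seconds (one EDF data record per second).  Each channel is scaled to
    its own physical min/max, so the round-trip error is at most one part
    in 2^16 of the channel range.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9 or fs_i <= 0:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    if n_samp % fs_i:
        raise ValueError("EDF writer needs a whole number of seconds of data")
    if len(labels) != n_ch:
        raise ValueError("labels length must match channel count")
    n_rec = n_samp // fs_i
    if physical_dims is None:
        physical_dims = ["uV"] * n_ch

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _pad("0", 8),                      # version
        _pad("X X X X", 80),               # patient id (anonymous)
        _pad("Startdate X X X X", 80),     # recording id
        _pad("01.01.00", 8),               # start date
        _pad("00.00.00", 8),               # start time
        _pad(str(256 * (n_ch + 1)), 8),    # header bytes
        _pad("", 44),                      # reserved
        _pad(str(n_rec), 8),               # number of data records
        _pad("1", 8),                      # record duration, seconds
        _pad(str(n_ch), 4),                # number of signals
    ])
    fields = [
        ("", 16, labels),
        ("", 80, ["" for _ in range(n_ch)]),          # transducer
        ("", 8, physical_dims),
        ("", 8, [f"{v:.6g}"[:8] for v in pmin]),
        ("", 8, [f"{v:.6g}"[:8] for v in pmax]),
        ("", 8, [str(dmin)] * n_ch),
        ("", 8, [str(dmax)] * n_ch),
        ("", 80, ["" for _ in range(n_ch)]),          # prefiltering
        ("", 8, [str(fs_i)] * n_ch),
        ("", 32, ["" for _ in range(n_ch)]),          # reserved
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values)
        for _, width, values in fields
    )

    # interleave: record r holds fs samples of ch0, then ch1, ...
    records = digital.reshape(n_ch, n_rec, fs_i).transpose(1, 0, 2)
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        f.write(records.tobytes())
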
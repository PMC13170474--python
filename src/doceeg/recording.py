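"""In-memory containers for multichannel EEG and epoched data, plus file I/O.

Recordings are stored channel x sample in microvolts. The text interchange
format is a tab-separated channel-by-sample matrix with a JSON sidecar
(same stem, ``.json``) carrying sampling rate, channel labels and the
subject / group / phase annotation. EDF files can be read through MNE when
it is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import EmptyDataError, InvalidInputError, InvalidParameterError

GROUPS = ("esketamine", "propofol")
PHASES = ("preoperative", "maintenance", "recovery")

# 64-channel montage following the extended international 10-20 layout
# (standard ANT/BioSemi-style ordering).
STANDARD_1020_64 = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
)


def default_labels(n_channels: int) -> list[str]:
    """First ``n_channels`` labels of the 64-channel 10-20 montage.

    Beyond 64 channels, synthetic ``EXT{i}`` labels are appended.
    """
    labels = list(STANDARD_1020_64[:n_channels])
    labels += [f"EXT{i}" for i in range(len(labels), n_channels)]
    return labels


@dataclass
class EEGRecording:
    """One subject/phase multichannel recording (channel x sample, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D channel x sample matrix")
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = default_labels(self.data.shape[0])
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidInputError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=float),
                       fs=self.fs if fs is None else fs)


@dataclass
class EpochSet:
    """Fixed-length sliding-window epochs cut from one recording.

    ``epochs`` is epoch x channel x sample; ``starts`` holds the start time of
    each *kept* epoch in seconds; ``kept_mask`` is indexed over the full
    candidate grid (before rejection).
    """

    epochs: np.ndarray
    fs: float
    window: float
    overlap: float
    starts: np.ndarray
    kept_mask: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise InvalidInputError("epochs must be epoch x channel x sample")
        expected = int(round(self.window * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise InvalidInputError(
                f"epoch length {self.epochs.shape[2]} != window*fs = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def require_nonempty(self) -> None:
        if self.n_epochs == 0:
            raise EmptyDataError("no epochs survive; cannot continue")


def save_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as TSV (channels x samples) with a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, fmt="%.6g", delimiter="\t")
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "group": rec.group,
        "phase": rec.phase,
        "units": "microvolts",
        "layout": "channels x samples",
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path: str | Path) -> EEGRecording:
    """Read a TSV recording written by :func:`save_recording`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise InvalidInputError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group"),
        phase=meta.get("phase"),
    )


def read_edf(path: str | Path, subject_id: str = "", group: str | None = None,
             phase: str | None = None) -> EEGRecording:
    """Read an EDF recording via MNE (optional dependency).

    Values are converted from MNE's volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        group=group,
        phase=phase,
    )
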
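"""Recording containers, band-pass filtering, epoching, and file readers.

The preprocessing here is the automatable subset of a typical resting-state
EEG pipeline: zero-phase band-pass filtering and segmentation into
fixed-length non-overlapping epochs, plus an optional amplitude-threshold
epoch rejection.  Expert artifact screening (ICA component review) is
deliberately out of scope; synthetic cohorts are artifact-free by
construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "Epoch",
    "bandpass_filter",
    "segment_epochs",
    "reject_epochs_by_amplitude",
    "read_csv_recording",
    "read_edf_recording",
    "load_cohort_dir",
]


@dataclass
class EEGRecording:
    """A labeled multichannel recording (channels x samples)."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length window of a recording, one classification sample."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    window_seconds: float
    subject_id: str = ""
    group: str = "unknown"
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = int(round(self.window_seconds * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch has {self.data.shape[1]} samples, expected {expected}"
            )


def bandpass_filter(rec: EEGRecording, low: float = 0.1,
                    high: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    A 4th-order design applied forward and backward (``sosfiltfilt``), so
    the pass band is phase-distortion free.  Band edges must satisfy
    0 < low < high < fs/2.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(
            f"band edges ({low}, {high}) must satisfy 0 < low < high < fs/2 "
            f"= {rec.fs / 2}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(filtered, rec.fs, list(rec.channel_names),
                        rec.subject_id, rec.group)


def segment_epochs(rec: EEGRecording,
                   window_seconds: float = 10.0) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one window is dropped.  A recording
    shorter than one window is an error.
    """
    win = int(round(window_seconds * rec.fs))
    n = rec.n_samples // win
    if n == 0:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than one "
            f"{window_seconds:.1f} s window"
        )
    return [
        Epoch(rec.data[:, i * win:(i + 1) * win], rec.fs,
              list(rec.channel_names), window_seconds,
              rec.subject_id, rec.group, index=i)
        for i in range(n)
    ]


def reject_epochs_by_amplitude(epochs: list[Epoch],
                               threshold: float) -> list[Epoch]:
    """Drop epochs whose peak absolute value on any channel exceeds threshold.

    Order is preserved.  Rejecting everything produces an empty list with a
    warning, not an error.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    kept = [e for e in epochs if np.abs(e.data).max() <= threshold]
    if epochs and not kept:
        warnings.warn("amplitude rejection removed every epoch",
                      stacklevel=2)
    return kept


def read_csv_recording(csv_path: str | Path) -> EEGRecording:
    """Read a CSV matrix (rows = channels) with a ``.json`` sidecar.

    The sidecar must provide ``fs`` and ``channel_names``; ``subject_id``
    and ``group`` are optional.
    """
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        subject_id=str(meta.get("subject_id", csv_path.stem)),
        group=str(meta.get("group", "unknown")),
    )


def read_edf_recording(edf_path: str | Path, group: str = "unknown"
                       ) -> EEGRecording:
    """Read a multichannel EDF recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF files requires the optional dependency 'mne'"
        ) from exc
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=Path(edf_path).stem,
        group=group,
    )


def load_cohort_dir(directory: str | Path) -> list[EEGRecording]:
    """Load a cohort written by :func:`mseeg.synthetic.write_cohort_csv`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    return [read_csv_recording(directory / e["file"])
            for e in manifest["subjects"]]
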
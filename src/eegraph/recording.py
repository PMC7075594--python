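"""Epoched multichannel recordings: container, artifact rejection and file I/O.

A recording is a ``(n_epochs, n_channels, n_samples)`` array with channel
labels and a sampling rate.  Epochs are consecutive fixed-length segments of
the continuous signal.  The on-disk format is a plain delimited text file so
every intermediate artifact stays human-inspectable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EpochedRecording",
    "reject_artifacts",
    "write_recording",
    "read_recording",
]


@dataclass
class EpochedRecording:
    """Channel-labelled epoch array with sampling rate."""

    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray  # shape (n_epochs, n_channels, n_samples)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (epochs, channels, samples), got shape {self.data.shape}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but data has "
                f"{self.data.shape[1]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_length(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.sampling_rate


def reject_artifacts(
    recording: EpochedRecording,
    threshold: float = 100.0,
    subject_id: str | None = None,
) -> tuple[EpochedRecording, int]:
    """Drop epochs whose absolute amplitude exceeds ``threshold`` on any channel.

    The comparison is strict: an epoch whose maximum equals the threshold
    exactly is kept.  The threshold is in the recording's native amplitude
    unit (conventionally microvolts for scalp EEG).

    Returns the surviving recording (epoch order preserved) and the number of
    dropped epochs.  Raises ``ValueError`` if no epoch survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(recording.data).max(axis=(1, 2))
    keep = peak <= threshold
    n_dropped = int((~keep).sum())
    if not keep.any():
        who = f" for subject {subject_id!r}" if subject_id else ""
        raise ValueError(
            f"artifact rejection at threshold {threshold} removed all "
            f"{recording.n_epochs} epochs{who}"
        )
    if n_dropped == 0:
        return recording, 0
    return replace(recording, data=recording.data[keep]), n_dropped


_MAGIC = "# eegraph-recording v1"


def write_recording(recording: EpochedRecording, path: str | Path) -> None:
    """Write a recording as delimited text (epoch-major rows, channel columns)."""
    path = Path(path)
    flat = recording.data.transpose(0, 2, 1).reshape(-1, recording.n_channels)
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(
        f"# sampling_rate={recording.sampling_rate!r} "
        f"n_epochs={recording.n_epochs} n_samples={recording.n_samples}\n"
    )
    buf.write(",".join(recording.channel_labels) + "\n")
    np.savetxt(buf, flat, fmt="%.17g", delimiter=",")  # exact float64 round-trip
    path.write_text(buf.getvalue())


def _read_delimited(path: Path) -> EpochedRecording:
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != _MAGIC:
            raise ValueError(f"{path}: malformed header (expected {_MAGIC!r})")
        meta_line = fh.readline().strip()
        meta: dict[str, str] = {}
        for token in meta_line.lstrip("# ").split():
            key, _, value = token.partition("=")
            meta[key] = value
        labels = tuple(fh.readline().strip().split(","))
        flat = np.loadtxt(fh, delimiter=",", ndmin=2)
    try:
        sampling_rate = float(meta["sampling_rate"])
        n_epochs = int(meta["n_epochs"])
        n_samples = int(meta["n_samples"])
    except KeyError as exc:
        raise ValueError(f"{path}: header missing field {exc.args[0]!r}") from None
    if flat.shape != (n_epochs * n_samples, len(labels)):
        raise ValueError(
            f"{path}: data shape {flat.shape} inconsistent with header "
            f"({n_epochs} epochs x {n_samples} samples x {len(labels)} channels)"
        )
    data = flat.reshape(n_epochs, n_samples, len(labels)).transpose(0, 2, 1)
    return EpochedRecording(labels, sampling_rate, data)


def _read_edf(path: Path, epoch_length: float) -> EpochedRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires the 'mne' package (pip install eegraph[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sampling_rate = float(raw.info["sfreq"])
    signal = raw.get_data()  # (channels, samples)
    n_samples = int(round(sampling_rate * epoch_length))
    if n_samples <= 0 or sampling_rate * epoch_length != n_samples:
        raise ValueError("sampling_rate x epoch_length must be an integer")
    n_epochs = signal.shape[1] // n_samples
    if n_epochs == 0:
        raise ValueError(f"{path}: shorter than one {epoch_length} s epoch")
    data = (
        signal[:, : n_epochs * n_samples]
        .reshape(signal.shape[0], n_epochs, n_samples)
        .transpose(1, 0, 2)
    )
    return EpochedRecording(tuple(raw.ch_names), sampling_rate, data)


def read_recording(
    path: str | Path,
    format: str = "auto",
    epoch_length: float = 2.0,
    expected_channels: Sequence[str] | None = None,
) -> EpochedRecording:
    """Read a recording from delimited text or EDF.

    Parameters
    ----------
    format
        ``"delimited"``, ``"edf"`` or ``"auto"`` (by file suffix).
    epoch_length
        Segmentation length in seconds for continuous (EDF) input; ignored
        for delimited files, which store epoch boundaries in their header.
    expected_channels
        If given, the file's labels must match exactly (order included).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "delimited":
        rec = _read_delimited(path)
    elif format == "edf":
        rec = _read_edf(path, epoch_length)
    else:
        raise ValueError(f"unknown format {format!r}")
    if expected_channels is not None:
        expected = tuple(expected_channels)
        if rec.channel_labels != expected:
            missing = sorted(set(expected) - set(rec.channel_labels))
            raise ValueError(
                f"{path}: channel labels do not match expectation; "
                f"missing {missing or 'none'}, got {len(rec.channel_labels)} "
                f"channels where {len(expected)} were declared"
            )
    return rec
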
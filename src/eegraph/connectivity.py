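"""Phase-lag-index (PLI) functional connectivity.

The PLI between two signals is the absolute time-average of the sign of
their wrapped instantaneous phase difference,

    PLI(x_i, x_j) = | (1/m) sum_t sign(dphi_ij(t)) |,   dphi in (-pi, pi],

which is 0 when the phase difference is symmetric around zero (including
exactly zero-lag coupling, e.g. volume conduction) and 1 when one signal
consistently leads the other.  Signals are band-pass filtered per epoch,
phases come from the analytic (Hilbert) signal, per-epoch PLI matrices are
averaged into the subject's connectivity matrix, and matrices are summarised
globally (off-diagonal mean) or by regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .montage import BandDefinition, RoiMap
from .recording import EpochedRecording

__all__ = [
    "PhaseEpochs",
    "ConnectivityMatrix",
    "bandpass_epochs",
    "instantaneous_phase",
    "average_pli_matrix",
    "global_average_pli",
    "regional_pli",
    "subject_connectivity",
]

#: Interval (seconds) trimmed from each end of every epoch before PLI
#: summation, suppressing analytic-signal edge effects.
DEFAULT_EDGE_TRIM = 0.1


@dataclass
class PhaseEpochs:
    """Instantaneous phases, ``(n_epochs, n_channels, n_samples)``, radians."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("phase array must be (epochs, channels, samples)")


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band PLI matrix with zero diagonal and entries in [0, 1]."""

    band: BandDefinition
    channel_labels: tuple[str, ...]
    values: np.ndarray
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} channel labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("PLI entries must lie in [0, 1]")


def _design_bandpass(band: BandDefinition, sampling_rate: float, order: int = 4):
    band.validate_for(sampling_rate)
    return sps.butter(
        order,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_epochs(
    recording: EpochedRecording, band: BandDefinition, order: int = 4
) -> EpochedRecording:
    """Zero-phase band-pass of every channel of every epoch.

    A Butterworth filter is applied forward and backward (``sosfiltfilt``),
    cancelling the phase response; the output shape equals the input shape.
    """
    sos = _design_bandpass(band, recording.sampling_rate, order)
    # sosfiltfilt pads by reflection; the epoch must exceed the pad length.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"epoch of {recording.n_samples} samples too short for zero-phase "
            f"filtering (needs > {padlen})"
        )
    filtered = sps.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=np.ascontiguousarray(filtered))


def instantaneous_phase(band_epochs: EpochedRecording) -> PhaseEpochs:
    """Analytic-signal phase of band-limited epochs."""
    analytic = sps.hilbert(band_epochs.data, axis=-1)
    return PhaseEpochs(np.angle(analytic), band_epochs.sampling_rate)


def _pli_one_epoch(phases: np.ndarray) -> np.ndarray:
    # sign(sin(phi_i - phi_j)) computed without forming wrapped differences:
    # sin(a - b) = sin a cos b - cos a sin b.  Exactly zero differences give
    # sign 0, so identical phase series yield PLI 0.  The cross products run
    # in single precision (sign extraction is insensitive to it); the sign
    # average accumulates in double.
    ph32 = phases.astype(np.float32)
    s, c = np.sin(ph32), np.cos(ph32)
    cross = s[:, None, :] * c[None, :, :]
    cross -= c[:, None, :] * s[None, :, :]
    return np.abs(np.sign(cross).mean(axis=-1, dtype=np.float64))


def average_pli_matrix(
    phases: PhaseEpochs,
    band: BandDefinition,
    channel_labels: tuple[str, ...],
    edge_trim: float = DEFAULT_EDGE_TRIM,
) -> ConnectivityMatrix:
    """Per-epoch PLI matrices averaged elementwise over epochs.

    ``edge_trim`` seconds are excluded at both ends of each epoch before the
    sign average (analytic-signal edges are unreliable there).
    """
    data = phases.data
    n_epochs, n_channels, n_samples = data.shape
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    if n_channels < 2:
        raise ValueError("PLI requires at least two channels (no pairs otherwise)")
    trim = int(round(edge_trim * phases.sampling_rate))
    if 2 * trim >= n_samples:
        raise ValueError(
            f"edge trim of {trim} samples per side leaves no samples "
            f"in a {n_samples}-sample epoch"
        )
    sl = slice(trim, n_samples - trim) if trim else slice(None)
    acc = np.zeros((n_channels, n_channels))
    for e in range(n_epochs):
        acc += _pli_one_epoch(data[e, :, sl])
    acc /= n_epochs
    np.fill_diagonal(acc, 0.0)
    # enforce exact symmetry against floating-point jitter
    acc = 0.5 * (acc + acc.T)
    return ConnectivityMatrix(band, tuple(channel_labels), acc, n_epochs)


def global_average_pli(matrix: ConnectivityMatrix) -> float:
    """Mean over the off-diagonal cells of the connectivity matrix."""
    v = matrix.values
    n = v.shape[0]
    return float((v.sum() - np.trace(v)) / (n * (n - 1)))


def regional_pli(
    matrix: ConnectivityMatrix,
    roi_map: RoiMap,
    region_a: str,
    region_b: str | None = None,
) -> float:
    """Regional connectivity summary.

    With one region: the mean PLI over unordered electrode pairs inside it
    (the regional *average* PLI).  With two regions: the mean over all cross
    pairs with one electrode in each (the regional PLI between them).
    """
    labels = matrix.channel_labels
    if region_b is None or region_b == region_a:
        pairs = roi_map.within_pairs(region_a, labels)
    else:
        pairs = roi_map.between_pairs(region_a, region_b, labels)
    vals = [matrix.values[i, j] for i, j in pairs]
    return float(np.mean(vals))


def subject_connectivity(
    recording: EpochedRecording,
    band: BandDefinition,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    filter_order: int = 4,
) -> ConnectivityMatrix:
    """Band-pass -> analytic phase -> epoch-averaged PLI matrix."""
    narrow = bandpass_epochs(recording, band, order=filter_order)
    phases = instantaneous_phase(narrow)
    return average_pli_matrix(
        phases, band, recording.channel_labels, edge_trim=edge_trim
    )
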
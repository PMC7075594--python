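"""Electrode montage, frequency bands and region-of-interest bookkeeping.

The default layout is a 64-channel extended 10-20 montage partitioned into
twelve scalp regions (frontal, temporal, central, parietal and occipital
strips).  Regions are used to summarise connectivity at a coarser spatial
scale than single electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

__all__ = [
    "BandDefinition",
    "RoiMap",
    "DEFAULT_BANDS",
    "BAND_MAP",
    "DEFAULT_CHANNELS",
    "DEFAULT_ROI_MAP",
    "spectral_resolution",
]

# Twelve regions of interest and their electrodes.  Note that this mapping
# intentionally follows a convention in which the "right frontal" strip
# carries odd-numbered labels; it is a default and fully user-overridable.
_ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    "RF": ("Fp1", "AF7", "AF3", "F7", "F5", "F3"),
    "MF": ("F1", "Fz", "F2", "FC1", "FC2"),
    "LF": ("F4", "Fp2", "AF4", "AF8", "F6", "F8"),
    "LT": ("FT9", "FT7", "T7", "TP7", "TP9"),
    "LC": ("FC5", "FC3", "C5", "C3", "CP5", "CP3"),
    "MC": ("C1", "Cz", "C2", "CP1", "CPz", "CP2"),
    "RC": ("FC4", "FC6", "C4", "C6", "CP4", "CP6"),
    "RT": ("FT10", "FT8", "T8", "TP8", "TP10"),
    "LP": ("P7", "P5", "P3", "PO7", "PO3"),
    "MP": ("P1", "Pz", "P2", "POz"),
    "RP": ("P4", "P6", "P8", "PO4", "PO8"),
    "O": ("PO9", "O1", "Oz", "O2", "PO10"),
}

#: Default channel order: concatenation of the twelve regions.
DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    label for labels in _ROI_CHANNELS.values() for label in labels
)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low_hz, high_hz)`` used for band-pass filtering."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )

    def validate_for(self, sampling_rate: float) -> None:
        """Raise if the band does not fit under the Nyquist frequency."""
        if self.high_hz >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz exceeds "
                f"Nyquist ({sampling_rate / 2} Hz)"
            )


#: The canonical analysis bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("lower_alpha", 8.0, 10.0),
    BandDefinition("upper_alpha", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

BAND_MAP: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class RoiMap:
    """Ordered map of region name -> electrode labels.

    Regions must be pairwise disjoint.  ``validate_against`` additionally
    checks that every listed electrode exists in a given recording.
    """

    regions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_ROI_CHANNELS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, labels in self.regions.items():
            if not labels:
                raise ValueError(f"region {name!r} is empty")
            overlap = seen.intersection(labels)
            if overlap:
                raise ValueError(f"regions overlap on {sorted(overlap)}")
            seen.update(labels)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def labels(self, region: str) -> tuple[str, ...]:
        try:
            return tuple(self.regions[region])
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def validate_against(self, channel_labels: Sequence[str]) -> None:
        available = set(channel_labels)
        for name, labels in self.regions.items():
            missing = [l for l in labels if l not in available]
            if missing:
                raise ValueError(
                    f"region {name!r} lists electrodes absent from the "
                    f"recording: {missing}"
                )

    def indices(self, region: str, channel_labels: Sequence[str]) -> list[int]:
        labels = self.labels(region)  # KeyError for unknown regions
        index = {label: i for i, label in enumerate(channel_labels)}
        try:
            return [index[l] for l in labels]
        except KeyError as exc:
            raise ValueError(
                f"electrode {exc.args[0]!r} of region {region!r} not in recording"
            ) from None

    def within_pairs(
        self, region: str, channel_labels: Sequence[str]
    ) -> list[tuple[int, int]]:
        """Unordered electrode-index pairs inside ``region``."""
        idx = self.indices(region, channel_labels)
        if len(idx) < 2:
            raise ValueError(f"region {region!r} has fewer than two electrodes")
        return list(combinations(idx, 2))

    def between_pairs(
        self, region_a: str, region_b: str, channel_labels: Sequence[str]
    ) -> list[tuple[int, int]]:
        """All cross pairs with one electrode in each region."""
        if region_a == region_b:
            raise ValueError("between_pairs requires two distinct regions")
        ia = self.indices(region_a, channel_labels)
        ib = self.indices(region_b, channel_labels)
        return [(i, j) for i in ia for j in ib]

    def region_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.region_names, 2))


DEFAULT_ROI_MAP = RoiMap()


def spectral_resolution(sampling_rate: float, n_points: int = 1024) -> float:
    """Frequency resolution (Hz) of an ``n_points`` spectral window.

    Provided for bookkeeping alongside the time-domain phase pipeline; e.g.
    500 Hz / 1024 points = 0.488 Hz.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    return sampling_rate / n_points
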
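"""Synthetic two-group cohorts of phase-coupled EEG and cognitive scores.

No public dataset accompanies the analysis this package implements, so the
cohort generator produces surrogate data with the statistical structure the
downstream pipeline assumes:

* Per band, each channel is a mixture of band-limited analytic oscillators,
  each applied with a constant per-channel phase lag (nonzero lags are what
  a lag-sensitive estimator like PLI can see):

  - a *global* oscillator at the smallest off-diagonal entry of the
    pairwise coupling matrix (the baseline every pair shares);
  - one oscillator per ROI *region*, mixed by the region's own channels at
    the "within" weight and by channels of coupled remote regions at the
    "between" weight -- this is what gives dense regional blocks a strong
    shared fraction (dedicated per-pair sources mathematically cannot:
    each pair's share of a channel with k partners is at most 1/k);
  - a *dedicated* oscillator for any pair whose matrix entry exceeds the
    global floor, with the band's constant pairwise phase offset applied
    exactly in the analytic domain;
  - an *independent* oscillator taking up the remainder of the channel's
    unit weight budget, plus white sensor noise.

  Expected PLI of a pair increases with its coupling at the default
  operating point, and reaches 1 for a fully coupled noise-free pair.
* Oscillators are band-limited Gaussian noise (Gaussian spectral bumps with
  randomized center frequencies inside the band), not pure tones: phase
  estimation faces realistic jitter, and the center-frequency spread makes
  uncoupled phase differences drift through whole cycles per epoch, keeping
  the uncoupled PLI baseline low.
* The default group contrast is confined to the delta band: patients have a
  mild diffuse attenuation of every shared weight (broad hyposynchrony) and
  a strong (x0.7) weakening of the right-frontal structure -- within-RF and
  the RF<->right-parietal / RF<->left-central couplings -- emulating a
  localized fronto-parietal disconnection on top of a global decrease.
* Cognitive subtest scores are drawn independently per subject from normal
  distributions whose group means and SDs default to the published
  demographics of the cohort being emulated.

One global seed expands into per-subject substreams by counter-based
spawning, so a given (spec, seed) always yields a bit-identical cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .montage import (
    DEFAULT_BANDS,
    DEFAULT_CHANNELS,
    DEFAULT_ROI_MAP,
    BandDefinition,
    RoiMap,
)
from .recording import EpochedRecording, write_recording

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "default_band_coupling",
    "default_region_coupling",
    "default_cognitive_distributions",
    "generate_cohort",
    "generate_cognitive_scores",
    "write_cohort",
    "read_cohort_manifest",
]

CONTROL = "control"
PATIENT = "patient"

#: Baseline coupling shared by every channel pair (global oscillator weight).
FLOOR_COUPLING = 0.15
#: Weight with which a channel mixes its own region's oscillator.
WITHIN_REGION_WEIGHT = 0.5
#: Diffuse long-range coupling: weight on every remote region's oscillator.
BETWEEN_REGION_WEIGHT = 0.2
#: Elevated weight on the fronto-parietal / fronto-central contrast pairs.
CONTRAST_REGION_WEIGHT = 0.4
#: Multiplier applied to patients' delta coupling on the contrast structure.
PATIENT_DELTA_SCALE = 0.7
#: Mild diffuse delta hyposynchrony in patients: multiplier on *every*
#: shared coupling weight (floor and regional), producing the broad
#: decrease on which the localized fronto-parietal deficit sits.
PATIENT_GLOBAL_DELTA_SCALE = 0.9
#: Region pairs (plus within-RF) whose delta coupling is weakened in patients.
CONTRAST_REGION_PAIRS = (("RF", "RP"), ("RF", "LC"))

# Cognitive subtest score distributions (mean, SD) per group: four CogState
# subtests (reaction times in ms for DET/IDN, accuracy-based scores for
# ONB/OCL) and six NIH Toolbox T-scores.
_COGNITIVE_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    CONTROL: {
        "DET": (402.09, 92.22),
        "IDN": (577.57, 99.99),
        "ONB": (0.94, 0.06),
        "OCL": (0.9828, 0.08),
        "PVT": (58.16, 8.08),
        "ORRT": (56.05, 6.29),
        "LSWMT": (51.73, 9.82),
        "DCCST": (56.15, 9.94),
        "PSMT": (48.33, 12.43),
        "PCPST": (50.55, 12.87),
    },
    PATIENT: {
        "DET": (444.39, 166.939),
        "IDN": (693.81, 178.90),
        "ONB": (0.85, 0.09),
        "OCL": (0.59, 0.09),
        "PVT": (53.10, 10.63),
        "ORRT": (52.23, 6.13),
        "LSWMT": (45.36, 6.20),
        "DCCST": (48.76, 12.30),
        "PSMT": (40.13, 5.51),
        "PCPST": (43.23, 9.75),
    },
}


def default_cognitive_distributions() -> dict[str, dict[str, tuple[float, float]]]:
    return {g: dict(d) for g, d in _COGNITIVE_DEFAULTS.items()}


def default_band_coupling(
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> dict[str, dict[str, np.ndarray]]:
    """Default pairwise coupling: a uniform floor.

    The spatial structure of the default cohort (regional synchrony and the
    patients' localized delta-band contrast) lives in
    :func:`default_region_coupling`; the pairwise matrices carry only the
    global baseline, which in the patients' delta band is mildly attenuated
    (diffuse hyposynchrony).
    """
    labels = tuple(channel_labels)
    n = len(labels)
    base = np.full((n, n), FLOOR_COUPLING)
    np.fill_diagonal(base, 0.0)
    patient_floor = FLOOR_COUPLING * PATIENT_GLOBAL_DELTA_SCALE
    patient_delta = np.full((n, n), patient_floor)
    np.fill_diagonal(patient_delta, 0.0)
    return {
        CONTROL: {b.name: base.copy() for b in bands},
        PATIENT: {
            b.name: (patient_delta.copy() if b.name == "delta" else base.copy())
            for b in bands
        },
    }


def default_region_coupling(
    roi_map: RoiMap = DEFAULT_ROI_MAP,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> dict[str, dict[str, dict]]:
    """Region-level coupling for both groups.

    Every region's channels share that region's oscillator at
    ``WITHIN_REGION_WEIGHT``; the long-range contrast region pairs
    additionally exchange their oscillators at ``CONTRAST_REGION_WEIGHT``.
    Patients are identical to controls except that in the delta band the
    within-RF weight and the contrast-pair weights are multiplied by
    ``PATIENT_DELTA_SCALE`` (a localized fronto-parietal/central
    disconnection).
    """
    within = {r: WITHIN_REGION_WEIGHT for r in roi_map.region_names}
    between = {
        pair: BETWEEN_REGION_WEIGHT for pair in roi_map.region_pairs()
    }
    between.update(
        {pair: CONTRAST_REGION_WEIGHT for pair in CONTRAST_REGION_PAIRS}
    )
    base = {"within": within, "between": between}

    def _copy(d):
        return {"within": dict(d["within"]), "between": dict(d["between"])}

    patient_delta = {
        "within": {
            r: w * PATIENT_GLOBAL_DELTA_SCALE for r, w in within.items()
        },
        "between": {
            pair: w * PATIENT_GLOBAL_DELTA_SCALE for pair, w in between.items()
        },
    }
    patient_delta["within"]["RF"] = within["RF"] * PATIENT_DELTA_SCALE
    for pair in CONTRAST_REGION_PAIRS:
        patient_delta["between"][pair] = between[pair] * PATIENT_DELTA_SCALE

    return {
        CONTROL: {b.name: _copy(base) for b in bands},
        PATIENT: {
            b.name: (patient_delta if b.name == "delta" else _copy(base))
            for b in bands
        },
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``band_coupling`` maps group -> band name -> symmetric pairwise coupling
    matrix with zero diagonal and entries in [0, 1].  Its off-diagonal
    minimum becomes a single *global* oscillator every channel mixes at
    that weight; anything above the minimum gets a dedicated shared
    oscillator for that pair.  ``region_coupling`` (group -> band ->
    ``{"within": {region: w}, "between": {(R, Q): w}}``) adds one shared
    oscillator per region: each channel mixes its own region's oscillator
    at the region's "within" weight and a remote region's oscillator at
    the pair's "between" weight, each with a random constant per-channel
    phase lag.  ``phase_offsets`` maps band name -> constant pairwise phase
    lag in (0, pi) used for the dedicated pair oscillators.
    ``epochs_per_subject`` may be a fixed count or an inclusive
    ``(low, high)`` range sampled per subject.
    """

    n_controls: int = 27
    n_patients: int = 13
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 500.0
    epoch_length: float = 2.0
    epochs_per_subject: int | tuple[int, int] = 90
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_coupling: Mapping[str, Mapping[str, np.ndarray]] | None = None
    region_coupling: Mapping[str, Mapping[str, dict]] | None = None
    roi_map: RoiMap | None = None
    phase_offsets: Mapping[str, float] | None = None
    noise_sd: float = 0.5
    cognitive_distributions: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=default_cognitive_distributions
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be nonnegative")
        n_samp = self.sampling_rate * self.epoch_length
        if abs(n_samp - round(n_samp)) > 1e-9 or round(n_samp) < 1:
            raise ValueError(
                "sampling_rate x epoch_length must be a positive integer "
                f"sample count (got {n_samp})"
            )
        default_channels = self.channel_labels == DEFAULT_CHANNELS
        if self.band_coupling is None:
            if not default_channels:
                raise ValueError(
                    "band_coupling must be given explicitly for non-default "
                    "channel sets"
                )
            self.band_coupling = default_band_coupling(bands=self.bands)
            if self.region_coupling is None:
                self.region_coupling = default_region_coupling(bands=self.bands)
            if self.roi_map is None:
                self.roi_map = DEFAULT_ROI_MAP
        if self.region_coupling is not None:
            if self.roi_map is None:
                raise ValueError("region_coupling requires a roi_map")
            self.roi_map.validate_against(self.channel_labels)
            for group, per_band in self.region_coupling.items():
                for band_name, rc in per_band.items():
                    for r, wgt in rc.get("within", {}).items():
                        if r not in self.roi_map.regions:
                            raise ValueError(f"unknown region {r!r}")
                        if not (0 <= wgt <= 1):
                            raise ValueError(
                                f"region weight for {r!r} must be in [0, 1]"
                            )
                    for (ra, rb), wgt in rc.get("between", {}).items():
                        for r in (ra, rb):
                            if r not in self.roi_map.regions:
                                raise ValueError(f"unknown region {r!r}")
                        if not (0 <= wgt <= 1):
                            raise ValueError(
                                f"region weight for {(ra, rb)} must be in [0, 1]"
                            )
        if self.phase_offsets is None:
            self.phase_offsets = {b.name: np.pi / 4 for b in self.bands}
        n = len(self.channel_labels)
        for group, per_band in self.band_coupling.items():
            for band_name, mat in per_band.items():
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (n, n):
                    raise ValueError(
                        f"coupling[{group}][{band_name}] has shape {mat.shape}, "
                        f"expected ({n}, {n})"
                    )
                if not np.allclose(mat, mat.T, atol=1e-12):
                    raise ValueError(
                        f"coupling[{group}][{band_name}] is not symmetric"
                    )
                if np.any(np.diag(mat) != 0):
                    raise ValueError(
                        f"coupling[{group}][{band_name}] diagonal must be zero"
                    )
                if mat.min() < 0 or mat.max() > 1:
                    raise ValueError(
                        f"coupling[{group}][{band_name}] entries must be in [0, 1]"
                    )
        for band in self.bands:
            band.validate_for(self.sampling_rate)
            off = self.phase_offsets.get(band.name)
            if off is not None and not (0 < off < np.pi):
                raise ValueError(
                    f"phase offset for band {band.name!r} must lie in (0, pi)"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_length))


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    recording: EpochedRecording
    cognitive_scores: dict[str, float]


def _analytic_band_noise(
    rng: np.random.Generator,
    n_samples: int,
    centers: np.ndarray,
    widths: np.ndarray,
    sampling_rate: float,
) -> np.ndarray:
    """Analytic band-limited Gaussian noise, one oscillator per row.

    Oscillators are synthesised in the frequency domain: a complex Gaussian
    spectrum shaped by a Gaussian bump (center ``centers[i]``, full width at
    half maximum ``widths[i]``) on the positive frequencies only, so the
    inverse FFT is exactly analytic.  Real parts are normalised to unit
    standard deviation.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    n_rows = centers.size
    spec = rng.standard_normal((n_rows, freqs.size)) + 1j * rng.standard_normal(
        (n_rows, freqs.size)
    )
    sigma = widths[:, None] / 2.355  # FWHM -> Gaussian sigma
    spec *= np.exp(-0.5 * ((freqs[None, :] - centers[:, None]) / sigma) ** 2)
    spec[:, 0] = 0.0  # no DC
    full = np.zeros((n_rows, n_samples), dtype=complex)
    full[:, : freqs.size] = spec
    a = np.fft.ifft(full, axis=-1)
    sd = a.real.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return a / sd


def _coupling_structure(mat: np.ndarray):
    """Split a coupling matrix into a global floor and residual pairs."""
    n = mat.shape[0]
    off = mat[np.triu_indices(n, k=1)]
    floor = float(off.min()) if off.size else 0.0
    iu, ju = np.triu_indices(n, k=1)
    resid = mat[iu, ju] - floor
    keep = resid > 1e-12
    return floor, iu[keep], ju[keep], resid[keep]


def _region_weight_matrix(
    spec: CohortSpec, region_cfg: dict | None
) -> tuple[np.ndarray, list[str]] | None:
    """Channel-by-region mixing weights for the region oscillators.

    Column q holds each channel's weight on region q's oscillator: the
    "within" weight for the region's own channels, the "between" weight for
    channels of regions coupled to q, zero elsewhere.
    """
    if region_cfg is None:
        return None
    roi = spec.roi_map
    regions = list(roi.region_names)
    n_ch = len(spec.channel_labels)
    w = np.zeros((n_ch, len(regions)))
    for q, region in enumerate(regions):
        wgt = region_cfg.get("within", {}).get(region, 0.0)
        if wgt:
            w[roi.indices(region, spec.channel_labels), q] = wgt
    for (ra, rb), wgt in region_cfg.get("between", {}).items():
        if not wgt:
            continue
        w[roi.indices(ra, spec.channel_labels), regions.index(rb)] = wgt
        w[roi.indices(rb, spec.channel_labels), regions.index(ra)] = wgt
    if not w.any():
        return None
    return w, regions


def _subject_signal(
    spec: CohortSpec,
    coupling: Mapping[str, np.ndarray],
    region_coupling: Mapping[str, dict] | None,
    n_epochs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous multichannel signal, reshaped to epochs by the caller.

    Two seconds of warm-up are generated at each end and trimmed, so the
    filtering / analytic-signal transients of the oscillator construction
    never reach the returned epochs.
    """
    n_ch = len(spec.channel_labels)
    pad = int(round(2.0 * spec.sampling_rate))
    total = n_epochs * spec.n_samples + 2 * pad
    x = np.zeros((n_ch, total))
    for band in spec.bands:
        mat = np.asarray(coupling[band.name], dtype=float)
        floor, iu, ju, resid = _coupling_structure(mat)
        pair_lag = spec.phase_offsets.get(band.name, np.pi / 4)
        # Every oscillator occupies its own sub-band of the analysis band
        # (random center, FWHM one third of the band width).  Components
        # that are *not* shared by a pair therefore differ in center
        # frequency, so their phase differences drift through whole cycles
        # within an epoch and uncoupled pairs show the low PLI baseline of
        # real recordings rather than the large random-walk bias of
        # identically-centred narrowband noise.
        width = (band.high_hz - band.low_hz) / 3.0
        c_lo, c_hi = band.low_hz + width / 2, band.high_hz - width / 2

        if floor > 0:
            shared = _analytic_band_noise(
                rng, total,
                np.array([(band.low_hz + band.high_hz) / 2]),
                np.array([band.high_hz - band.low_hz]),
                spec.sampling_rate,
            )[0]
            # random constant per-channel lags; pairwise lag differences are
            # what makes the baseline visible to a lag-sensitive estimator
            theta = rng.uniform(0.25 * np.pi, 0.75 * np.pi, size=n_ch)
            x += floor * np.real(shared[None, :] * np.exp(-1j * theta[:, None]))

        region_w = _region_weight_matrix(
            spec, None if region_coupling is None else region_coupling.get(band.name)
        )
        if region_w is not None:
            w_mat, regions = region_w
            centers = rng.uniform(c_lo, c_hi, size=len(regions))
            region_osc = _analytic_band_noise(
                rng, total, centers, np.full(len(regions), width),
                spec.sampling_rate,
            )
            psi = rng.uniform(
                0.25 * np.pi, 0.75 * np.pi, size=w_mat.shape
            )
            for q in range(len(regions)):
                active = w_mat[:, q] > 0
                if not active.any():
                    continue
                x[active] += w_mat[active, q, None] * np.real(
                    region_osc[q][None, :]
                    * np.exp(-1j * psi[active, q, None])
                )

        if len(iu):
            # dedicated pair oscillators get a wider bump (2/3 of the band):
            # deep envelope nulls of very narrow noise degrade the phase
            # estimate of even a perfectly coupled pair
            pair_width = 2.0 * (band.high_hz - band.low_hz) / 3.0
            centers = rng.uniform(
                band.low_hz + pair_width / 2,
                band.high_hz - pair_width / 2,
                size=len(iu),
            )
            pair_osc = _analytic_band_noise(
                rng, total, centers, np.full(len(iu), pair_width),
                spec.sampling_rate,
            )
            contrib_lead = resid[:, None] * np.real(pair_osc)
            contrib_lag = resid[:, None] * np.real(
                pair_osc * np.exp(-1j * pair_lag)
            )
            np.add.at(x, iu, contrib_lead)
            np.add.at(x, ju, contrib_lag)

        indep_w = 1.0 - mat.max(axis=1)
        if region_w is not None:
            indep_w = np.minimum(
                indep_w, 1.0 - region_w[0].max(axis=1, initial=0.0)
            )
        indep_w = np.clip(indep_w, 0.0, None)
        if np.any(indep_w > 1e-12):
            centers = rng.uniform(c_lo, c_hi, size=n_ch)
            indep = _analytic_band_noise(
                rng, total, centers, np.full(n_ch, width), spec.sampling_rate
            )
            x += indep_w[:, None] * np.real(indep)
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=x.shape)
    return x[:, pad : total - pad]


def generate_cognitive_scores(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> dict[str, float]:
    """One subject's cognitive subtest scores, drawn independently per test."""
    try:
        dists = spec.cognitive_distributions[group]
    except KeyError:
        raise KeyError(f"group {group!r} has no cognitive distributions") from None
    return {
        name: float(rng.normal(mean, sd)) for name, (mean, sd) in dists.items()
    }


def _subject_epoch_count(spec: CohortSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.epochs_per_subject, tuple):
        lo, hi = spec.epochs_per_subject
        return int(rng.integers(lo, hi + 1))
    return int(spec.epochs_per_subject)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the full cohort: recordings plus cognitive scores.

    Subject substreams are spawned from the spec seed by index, so the
    cohort is reproducible and individual subjects are stable under group
    reordering.
    """
    subjects: list[SyntheticSubject] = []
    groups = [CONTROL] * spec.n_controls + [PATIENT] * spec.n_patients
    for idx, group in enumerate(groups):
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence(spec.seed, spawn_key=(idx,)))
        )
        n_epochs = _subject_epoch_count(spec, rng)
        region_cfg = (
            spec.region_coupling.get(group)
            if spec.region_coupling is not None
            else None
        )
        sig = _subject_signal(
            spec, spec.band_coupling[group], region_cfg, n_epochs, rng
        )
        data = (
            sig.reshape(len(spec.channel_labels), n_epochs, spec.n_samples)
            .transpose(1, 0, 2)
        )
        recording = EpochedRecording(
            spec.channel_labels, spec.sampling_rate, data
        )
        scores = generate_cognitive_scores(spec, group, rng)
        label = "C" if group == CONTROL else "P"
        subjects.append(
            SyntheticSubject(f"{label}{idx:03d}", group, recording, scores)
        )
    return subjects


def write_cohort(subjects: Sequence[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write recordings, a manifest CSV and a cognitive-score CSV.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "path"])
        for s in subjects:
            rec_path = out_dir / f"{s.subject_id}.csv"
            write_recording(s.recording, rec_path)
            writer.writerow([s.subject_id, s.group, rec_path.name])
    tests = sorted({t for s in subjects for t in s.cognitive_scores})
    with (out_dir / "cognitive_scores.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", *tests])
        for s in subjects:
            writer.writerow(
                [s.subject_id, s.group]
                + [f"{s.cognitive_scores[t]:.10g}" for t in tests]
            )
    return manifest


def read_cohort_manifest(manifest: str | Path) -> list[dict[str, str]]:
    """Rows of ``subject_id, group, path`` with paths resolved."""
    manifest = Path(manifest)
    rows: list[dict[str, str]] = []
    with manifest.open() as fh:
        for row in csv.DictReader(fh):
            row["path"] = str(manifest.parent / row["path"])
            rows.append(row)
    if not rows:
        raise ValueError(f"{manifest}: empty manifest")
    return rows
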
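"""Shared fixtures: small synthetic inputs built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import eegraph as eg


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_pair_spec(
    couplings: dict[tuple[int, int], float],
    n_channels: int = 4,
    band: str = "delta",
    epochs: int = 6,
    noise_sd: float = 0.5,
    seed: int = 0,
    floor: float = 0.0,
    **kwargs,
) -> eg.CohortSpec:
    """CohortSpec with explicit pairwise couplings on a toy channel set."""
    labels = tuple(f"ch{i}" for i in range(n_channels))
    mat = np.full((n_channels, n_channels), floor)
    np.fill_diagonal(mat, 0.0)
    for (i, j), c in couplings.items():
        mat[i, j] = mat[j, i] = c
    band_def = eg.BAND_MAP[band]
    return eg.CohortSpec(
        n_controls=kwargs.pop("n_controls", 1),
        n_patients=kwargs.pop("n_patients", 0),
        channel_labels=labels,
        bands=(band_def,),
        band_coupling={
            "control": {band: mat},
            "patient": {band: kwargs.pop("patient_mat", mat)},
        },
        phase_offsets={band: kwargs.pop("phase_offset", np.pi / 4)},
        noise_sd=noise_sd,
        epochs_per_subject=epochs,
        cognitive_distributions={
            "control": {"X": (0.0, 1.0)},
            "patient": {"X": (0.0, 1.0)},
        },
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def toy_connectivity():
    """3-channel connectivity matrix with off-diagonal 0.1/0.2/0.3."""
    vals = np.array(
        [[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]]
    )
    return eg.ConnectivityMatrix(
        eg.BAND_MAP["delta"], ("a", "b", "c"), vals, n_epochs_averaged=1
    )


def random_complete_graph(n: int, rng: np.random.Generator) -> eg.BrainGraph:
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return eg.BrainGraph(w)
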
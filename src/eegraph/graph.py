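"""Traditional weighted brain-graph topology.

A brain graph is the complete weighted graph on the electrodes with edge
weights equal to pairwise PLI.  Two classical measures are computed:

* the average weighted clustering coefficient
      C^w = (1/n) sum_i  [ sum_{k!=i} sum_{l!=i,k} w_ik w_il w_kl ]
                       / [ sum_{k!=i} sum_{l!=i,k} w_ik w_il ]
* the average weighted characteristic path length over ordered pairs,
      L^w = 1/(n(n-1)) sum_{u!=v} d(u, v),
  where path lengths use edge lengths 1/w (stronger coupling = shorter).

Both are normalized by their means over null graphs obtained by uniformly
reshuffling the upper-triangle weights, and the small-world index is the
ratio S = C^hat / L^hat; S > 1 indicates small-world organisation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BrainGraph",
    "TraditionalMetrics",
    "weighted_clustering",
    "weighted_path_length",
    "normalized_small_world",
]


@dataclass
class BrainGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0:
            raise ValueError("weights must be nonnegative")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != w.shape[0]:
                raise ValueError("label count does not match matrix size")

    @classmethod
    def from_connectivity(cls, matrix: ConnectivityMatrix) -> "BrainGraph":
        return cls(matrix.values.copy(), matrix.channel_labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class TraditionalMetrics:
    """Raw, null-mean and normalized clustering / path length, plus S."""

    Cw: float
    Lw: float
    Cw_null_mean: float
    Lw_null_mean: float
    Cw_hat: float
    Lw_hat: float
    S: float
    n_null: int
    seed: int | None


def weighted_clustering(graph: BrainGraph) -> float:
    """Average weighted clustering coefficient.

    Vertices with a zero denominator (no pair of positively weighted
    incident edges) contribute 0.
    """
    w = graph.weights
    n = graph.n
    if n < 3:
        raise ValueError("clustering needs at least three vertices")
    # numerator_i = (W^3)_ii ; denominator_i = (sum_k w_ik)^2 - sum_k w_ik^2
    numer = np.diagonal(w @ w @ w)
    row = w.sum(axis=1)
    denom = row**2 - (w**2).sum(axis=1)
    per_vertex = np.divide(
        numer, denom, out=np.zeros(n), where=denom > 1e-300
    )
    return float(per_vertex.mean())


def _distance_matrix(graph: BrainGraph) -> np.ndarray:
    w = graph.weights
    lengths = np.zeros_like(w)
    mask = w > 0
    lengths[mask] = 1.0 / w[mask]
    # zero weight = absent edge
    d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    return d


def weighted_path_length(graph: BrainGraph) -> float:
    """Average shortest-path length (edge length 1/w) over ordered pairs."""
    n = graph.n
    if n < 2:
        raise ValueError("path length needs at least two vertices")
    d = _distance_matrix(graph)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        n_comp, comp = connected_components(
            (graph.weights > 0).astype(int), directed=False
        )
        members = [list(np.flatnonzero(comp == c)) for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components: {members}")
    return float(d[off].mean())


def _shuffled(graph: BrainGraph, rng: np.random.Generator) -> BrainGraph:
    n = graph.n
    iu = np.triu_indices(n, k=1)
    vals = graph.weights[iu].copy()
    rng.shuffle(vals)
    w = np.zeros_like(graph.weights)
    w[iu] = vals
    w += w.T
    return BrainGraph(w, graph.labels)


def normalized_small_world(
    graph: BrainGraph, n_null: int = 50, seed: int | None = None
) -> TraditionalMetrics:
    """Reshuffle-normalized clustering, path length and small-world index.

    Each null graph permutes the multiset of upper-triangle weights uniformly
    at random (diagonal and symmetry preserved).  C^hat = C^w / <C^w>,
    L^hat = L^w / <L^w>, S = C^hat / L^hat.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    cw = weighted_clustering(graph)
    lw = weighted_path_length(graph)
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for i in range(n_null):
        # A shuffled null of a graph containing zero weights can come out
        # disconnected; resample it (complete positive graphs never do).
        for _attempt in range(100):
            null = _shuffled(graph, rng)
            try:
                l_null[i] = weighted_path_length(null)
            except ValueError:
                continue
            c_null[i] = weighted_clustering(null)
            break
        else:
            raise ValueError("could not draw a connected null graph")
    c_mean = float(c_null.mean())
    l_mean = float(l_null.mean())
    cw_hat = cw / c_mean
    lw_hat = lw / l_mean
    return TraditionalMetrics(
        Cw=cw,
        Lw=lw,
        Cw_null_mean=c_mean,
        Lw_null_mean=l_mean,
        Cw_hat=cw_hat,
        Lw_hat=lw_hat,
        S=cw_hat / lw_hat,
        n_null=n_null,
        seed=seed,
    )
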
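"""Maximum-weight spanning trees of brain graphs and their topology.

The spanning tree that maximises total PLI weight (equivalently, minimises
the sum of inverse weights) is the "backbone" of the connectivity graph.
It is extracted with Kruskal's algorithm under a deterministic tie-break,
its edge weights are then discarded, and the unweighted tree is summarised
by a standard measure suite (degree, eccentricity, betweenness, leaf
fraction, degree divergence, diameter, tree hierarchy).  Trees of different
subjects are compared with an asymmetric dissimilarity based on how far the
neighbours of each vertex in one tree are from that vertex in the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import BrainGraph

__all__ = [
    "SpanningTree",
    "TreeMetrics",
    "DissimilarityResult",
    "extract_mst",
    "tree_metrics",
    "tree_dissimilarity",
    "write_tree",
    "read_tree",
]


@dataclass
class SpanningTree:
    """Unweighted tree: ``n`` vertices and ``n - 1`` undirected edges."""

    n: int
    edges: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.edges = tuple((min(u, v), max(u, v)) for u, v in self.edges)
        if len(self.edges) != self.n - 1:
            raise ValueError(
                f"a spanning tree on {self.n} vertices needs {self.n - 1} "
                f"edges, got {len(self.edges)}"
            )
        g = self.to_networkx()
        if g.number_of_nodes() != self.n or not nx.is_connected(g):
            raise ValueError("edge list does not form a connected spanning tree")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass
class TreeMetrics:
    """Normalized tree measure suite (hop distances, weights ignored)."""

    k_star_max: float  # max degree / n
    e_star_avr: float  # mean eccentricity / (n - 1)
    bc_star_max: float  # max betweenness, normalized by 2/((n-1)(n-2))
    kappa: float  # degree divergence, sum k^2 / sum k
    d_star: float  # diameter / (n - 1)
    l_star: float  # leaf count / (n - 1)
    t_h: float  # tree hierarchy, l* / (2 bc*_max)
    diameter: int  # diameter in hops
    leaf_count: int

    def as_dict(self) -> dict[str, float]:
        return {
            "k_star_max": self.k_star_max,
            "e_star_avr": self.e_star_avr,
            "bc_star_max": self.bc_star_max,
            "kappa": self.kappa,
            "d_star": self.d_star,
            "l_star": self.l_star,
            "t_h": self.t_h,
        }


@dataclass
class DissimilarityResult:
    value: float
    subject_id: str | None = None
    reference_id: str | None = None


def write_tree(tree: SpanningTree, path) -> None:
    """Serialize a tree as an edge-list CSV (vertex labels if available)."""
    import csv
    from pathlib import Path

    labels = tree.labels or tuple(str(i) for i in range(tree.n))
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "v"])
        for u, v in tree.edges:
            writer.writerow([labels[u], labels[v]])


def read_tree(path) -> SpanningTree:
    """Read an edge-list CSV back into a tree."""
    import csv
    from pathlib import Path

    edges_by_label = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            edges_by_label.append((row["u"], row["v"]))
    labels = []
    for u, v in edges_by_label:
        for l in (u, v):
            if l not in labels:
                labels.append(l)
    labels = tuple(sorted(labels))
    index = {l: i for i, l in enumerate(labels)}
    edges = tuple((index[u], index[v]) for u, v in edges_by_label)
    return SpanningTree(len(labels), edges, labels)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def extract_mst(graph: BrainGraph) -> SpanningTree:
    """Maximum-total-weight spanning tree via Kruskal's algorithm.

    Candidate edges are sorted by (weight descending, smaller vertex index,
    larger vertex index), which makes the tree deterministic when weights
    tie.  Requires a connected (in practice complete) positive-weight graph.
    """
    n = graph.n
    if n < 2:
        raise ValueError("spanning tree needs at least two vertices")
    iu, ju = np.triu_indices(n, k=1)
    w = graph.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for idx in order:
        if w[idx] <= 0:
            break
        if uf.union(int(iu[idx]), int(ju[idx])):
            edges.append((int(iu[idx]), int(ju[idx])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("graph is not connected by positive-weight edges")
    return SpanningTree(n, tuple(edges), graph.labels)


def tree_metrics(tree: SpanningTree) -> TreeMetrics:
    """Compute the normalized measure suite of an unweighted tree."""
    n = tree.n
    if n < 3:
        raise ValueError("tree metrics need at least three vertices")
    g = tree.to_networkx()
    deg = tree.degrees()

    ecc = nx.eccentricity(g)
    ecc_arr = np.array([ecc[v] for v in range(n)], dtype=float)
    diameter = int(ecc_arr.max())

    # In a tree every pair has a unique shortest path; networkx's normalized
    # betweenness divides by (n-1)(n-2)/2, i.e. exactly the 2/((n-1)(n-2))
    # normalization used here.
    bc = nx.betweenness_centrality(g, normalized=True)
    bc_max = float(max(bc.values()))

    leaves = int((deg == 1).sum())
    k = deg.astype(float)
    return TreeMetrics(
        k_star_max=float(k.max()) / n,
        e_star_avr=float(ecc_arr.mean()) / (n - 1),
        bc_star_max=bc_max,
        kappa=float((k**2).sum() / k.sum()),
        d_star=diameter / (n - 1),
        l_star=leaves / (n - 1),
        t_h=(leaves / (n - 1)) / (2.0 * bc_max) if bc_max > 0 else float("nan"),
        diameter=diameter,
        leaf_count=leaves,
    )


def tree_dissimilarity(
    g_tree: SpanningTree,
    h_tree: SpanningTree,
    subject_id: str | None = None,
    reference_id: str | None = None,
) -> DissimilarityResult:
    """Dissimilarity D(G|H): how far H's neighbourhoods are spread in G.

        D(G|H) = (1/n) sum_i log10( mean_{v_j in N_H(v_i)} d_G(v_i, v_j) )

    with hop distances in G.  Zero iff every H-neighbour is a G-neighbour
    (in particular for identical trees); asymmetric in general.
    """
    if g_tree.n != h_tree.n:
        raise ValueError(
            f"trees have different vertex sets ({g_tree.n} vs {h_tree.n})"
        )
    n = g_tree.n
    g = g_tree.to_networkx()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    h_adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in h_tree.edges:
        h_adj[u].append(v)
        h_adj[v].append(u)
    total = 0.0
    for i in range(n):
        nbrs = h_adj[i]
        mean_d = np.mean([dist[i][j] for j in nbrs])
        total += np.log10(mean_d)
    return DissimilarityResult(total / n, subject_id, reference_id)
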
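"""Weighted graphs, walktrap community detection, and Newman modularity.

The same machinery serves two levels of the pipeline: patients are clustered
on the (dense, weighted) similarity matrix, and symptoms are later clustered
on each community's normalized concordance network.

Community detection is Pons–Latapy walktrap: short random walks (t steps, 4
by default) define a distance between nodes, communities are merged
agglomeratively (Ward-style), and the dendrogram is cut at the level of
maximum weighted modularity. Walktrap performs well on dense weighted
undirected networks such as similarity matrices, and is fully deterministic —
the algorithm uses walk *distributions*, not sampled walks, so no randomness
enters. The detection itself is delegated to igraph's reference C
implementation; modularity is computed here from the Newman formula

    Q = (1/2m) * sum_ij [W_ij - s_i s_j / (2m)] * delta(c_i, c_j)

with s the node strengths and 2m the total weight doubled. Nodes of zero
strength (isolates) carry no walk information and form singleton communities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .errors import ValidationError

__all__ = [
    "WeightedGraph",
    "CommunityPartition",
    "walktrap_communities",
    "modularity",
    "similarity_to_graph",
    "write_edgelist",
    "write_graphml",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph as a symmetric non-negative matrix, zero diagonal."""

    node_labels: tuple
    weights: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.node_labels)
        w = np.asarray(self.weights, dtype=np.float64)
        n = len(labels)
        if w.shape != (n, n):
            raise ValidationError(f"weights shape {w.shape}, expected ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        if w.size and w.min() < 0:
            raise ValidationError("edge weights must be non-negative")
        if not np.allclose(np.diagonal(w), 0.0):
            raise ValidationError("self-loops are not allowed (diagonal must be 0)")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def strengths(self) -> np.ndarray:
        """Per-node strength: the sum of incident edge weights."""
        return self.weights.sum(axis=1)

    def edges(self):
        """Yield (i, j, weight) for every positive-weight edge, i < j."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w > 0:
                yield int(i), int(j), float(w)

    def to_igraph(self) -> ig.Graph:
        edges = [(i, j) for i, j, _ in self.edges()]
        weights = [w for _, _, w in self.edges()]
        g = ig.Graph(edges, n=self.n_nodes)
        g.es["weight"] = weights
        g.vs["name"] = list(self.node_labels)
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for i, j, w in self.edges():
            g.add_edge(self.node_labels[i], self.node_labels[j], weight=w)
        return g


@dataclass(frozen=True)
class CommunityPartition:
    """Community label per node (contiguous ints from 0) plus the partition's Q."""

    labels: np.ndarray
    modularity: float
    n_communities: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        distinct = np.unique(labels)
        if labels.size and not np.array_equal(distinct, np.arange(len(distinct))):
            raise ValidationError("community labels must be contiguous from 0")
        if len(distinct) != self.n_communities:
            raise ValidationError("n_communities does not match distinct labels")
        object.__setattr__(self, "labels", labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.labels == community)


def _canonical_labels(membership) -> np.ndarray:
    """Relabel communities as contiguous integers in order of first appearance."""
    membership = np.asarray(membership)
    seen = {}
    out = np.empty(len(membership), dtype=np.int64)
    for idx, c in enumerate(membership):
        out[idx] = seen.setdefault(c, len(seen))
    return out


def modularity(g: WeightedGraph, labels) -> float:
    """Newman weighted modularity of a node partition.

    Q = (1/2m) sum_ij [W_ij - s_i s_j/(2m)] delta(c_i, c_j). Zero for the
    trivial one-community partition and, by convention, for graphs of zero
    total weight.
    """
    labels = np.asarray(labels)
    if labels.shape != (g.n_nodes,):
        raise ValidationError("labels must cover all nodes exactly once")
    two_m = g.weights.sum()
    if two_m == 0.0:
        return 0.0
    s = g.strengths
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += g.weights[np.ix_(idx, idx)].sum() / two_m - (s[idx].sum() / two_m) ** 2
    return float(q)


def walktrap_communities(
    g: WeightedGraph, steps: int = 4, seed: int | None = None
) -> CommunityPartition:
    """Walktrap community detection, cut at maximum modularity.

    Parameters
    ----------
    g : WeightedGraph
    steps : int
        Random-walk length t (default 4, the walktrap authors' default).
        Longer walks blur fine structure; shorter walks see only immediate
        neighborhoods.
    seed : int, optional
        Accepted for interface symmetry with stochastic detectors; walktrap is
        deterministic (walk distributions are computed exactly), so the seed
        has no effect.

    Notes
    -----
    Isolated nodes (zero strength) and disconnected components are handled
    natively: isolates come back as singleton communities. The returned
    modularity is recomputed with :func:`modularity` on the full graph, so the
    ``CommunityPartition`` invariant holds by construction.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    if g.n_nodes == 0:
        raise ValidationError("graph must have at least one node")
    graph = g.to_igraph()
    if graph.ecount() == 0:
        labels = np.arange(g.n_nodes, dtype=np.int64)
        return CommunityPartition(labels, 0.0, g.n_nodes)
    dendrogram = graph.community_walktrap(weights="weight", steps=steps)
    membership = dendrogram.as_clustering().membership
    labels = _canonical_labels(membership)
    return CommunityPartition(labels, modularity(g, labels), int(labels.max()) + 1)


def similarity_to_graph(s) -> WeightedGraph:
    """Turn a patient similarity matrix into a weighted graph.

    Off-diagonal similarities become edge weights (zero meaning no edge); the
    unit diagonal is dropped, i.e. self-similarity does not enter community
    detection.
    """
    w = np.array(s.values, dtype=np.float64)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(s.patient_ids, w)


def write_edgelist(g: WeightedGraph, path) -> None:
    """Write a weighted edge list CSV: source,target,weight."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for i, j, w in g.edges():
            writer.writerow([g.node_labels[i], g.node_labels[j], repr(w)])


def write_graphml(g: WeightedGraph, path) -> None:
    """Write the graph (isolates included) as GraphML via networkx."""
    import networkx as nx

    nx.write_graphml(g.to_networkx(), path)
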
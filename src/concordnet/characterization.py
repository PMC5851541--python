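"""Centralities, z-standardization, bridge classification, symptom clusters.

Each community concordance network is described with three weighted-graph
centralities from network psychometrics:

* **strength** — the sum of a symptom's edge weights: how much it co-occurs
  with everything else; high strength marks core symptoms of the community.
* **betweenness** — Freeman/Brandes shortest-path betweenness with edge
  lengths 1/weight (stronger co-occurrence = shorter distance): the number of
  geodesics between other symptom pairs passing through the symptom. This is
  the direct measure of how *bridge-like* a symptom is.
* **closeness** — inverse average geodesic distance to the other symptoms
  (Wasserman–Faust scaled on disconnected networks), a smoothed companion to
  strength.

Each statistic is z-standardized by pooling its values across all compared
community networks (the networks share the [0, 1] weight scale, so pooled
standardization makes communities comparable). Classification is descriptive,
not inferential: a symptom is a *bridge* when its z-betweenness is at least 2
standard deviations above the pooled mean, and *highly central* when both
z-strength and z-closeness are.

Within-community symptom clusters are found by the same walktrap detector
used for patients, applied to the normalized weight matrix; each solution's
modularity is comparable between communities because of the shared scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .aggregation import CommunityConcordanceNetwork
from .errors import ValidationError
from .graph_community import WeightedGraph, walktrap_communities

__all__ = [
    "CentralityProfile",
    "SymptomClusterSolution",
    "strength",
    "shortest_path_distances",
    "betweenness",
    "closeness",
    "z_standardize",
    "classify_symptoms",
    "characterize_communities",
    "detect_symptom_clusters",
    "centrality_table",
]


@dataclass
class CentralityProfile:
    """Raw and standardized centralities for one community's symptoms."""

    community_id: int
    symptom_labels: tuple
    betweenness: np.ndarray
    strength: np.ndarray
    closeness: np.ndarray
    z_betweenness: np.ndarray | None = None
    z_strength: np.ndarray | None = None
    z_closeness: np.ndarray | None = None
    is_bridge: np.ndarray | None = None
    is_highly_central: np.ndarray | None = None

    def bridge_symptoms(self) -> list:
        if self.is_bridge is None:
            raise ValidationError("profile has not been classified yet")
        return [s for s, b in zip(self.symptom_labels, self.is_bridge) if b]

    def highly_central_symptoms(self) -> list:
        if self.is_highly_central is None:
            raise ValidationError("profile has not been classified yet")
        return [s for s, b in zip(self.symptom_labels, self.is_highly_central) if b]


@dataclass(frozen=True)
class SymptomClusterSolution:
    """Walktrap symptom clusters within one community network."""

    community_id: int
    symptom_labels: tuple
    labels: np.ndarray
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _length_graph(net: CommunityConcordanceNetwork) -> nx.Graph:
    """networkx view with edge attribute ``length`` = 1/weight."""
    g = nx.Graph()
    g.add_nodes_from(range(net.k))
    w = net.normalized_weights
    iu, ju = np.triu_indices(net.k, 1)
    for i, j in zip(iu, ju):
        if w[i, j] > 0:
            g.add_edge(int(i), int(j), weight=float(w[i, j]), length=1.0 / float(w[i, j]))
    return g


def strength(net: CommunityConcordanceNetwork) -> np.ndarray:
    """Per-symptom strength: row sums of the normalized weight matrix."""
    return net.normalized_weights.sum(axis=1)


def shortest_path_distances(net: CommunityConcordanceNetwork) -> np.ndarray:
    """All-pairs geodesic distances with edge length 1/weight.

    Zero-weight pairs have no edge; unreachable pairs get +inf; the diagonal
    is 0. Computed with Dijkstra (non-negative lengths).
    """
    w = net.normalized_weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w == 0, 1.0, w), 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def betweenness(net: CommunityConcordanceNetwork) -> np.ndarray:
    """Weighted shortest-path betweenness per symptom.

    For node v: sum over unordered pairs (s, t), s != t != v, of
    sigma_st(v)/sigma_st, where sigma_st counts geodesics (1/weight lengths)
    and sigma_st(v) those passing through v. Unreachable pairs contribute 0.
    """
    g = _length_graph(net)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(net.k)], dtype=np.float64)


def closeness(net: CommunityConcordanceNetwork) -> np.ndarray:
    """Wasserman–Faust closeness per symptom on 1/weight distances.

    For node i with r_i other reachable symptoms and total geodesic distance
    D_i to them: C_i = (r_i / D_i) * (r_i / (k - 1)). On a connected network
    this is the plain inverse average geodesic distance; isolates score 0.
    """
    g = _length_graph(net)
    cc = nx.closeness_centrality(g, distance="length", wf_improved=True)
    return np.array([cc[i] for i in range(net.k)], dtype=np.float64)


def z_standardize(profiles) -> list:
    """Standardize one statistic by pooling values across compared communities.

    Parameters
    ----------
    profiles : sequence of 1-d arrays
        One vector of per-symptom values per community.

    Returns
    -------
    list of ndarray
        Same shapes; the pooled values have mean 0 and population SD 1.
        If the pooled SD is zero the statistic carries no information: all
        z-scores are 0 and a warning is emitted.
    """
    profiles = [np.asarray(p, dtype=np.float64) for p in profiles]
    if not profiles:
        raise ValidationError("need at least one community profile")
    pooled = np.concatenate(profiles)
    mean = pooled.mean()
    sd = pooled.std()  # population SD: the communities are the whole universe
    if sd == 0.0 or np.ptp(pooled) == 0.0:
        warnings.warn(
            "pooled statistic is constant; all z-scores set to 0", stacklevel=2
        )
        return [np.zeros_like(p) for p in profiles]
    return [(p - mean) / sd for p in profiles]


def classify_symptoms(profile: CentralityProfile, threshold: float = 2.0) -> CentralityProfile:
    """Flag bridge and highly-central symptoms on a standardized profile.

    ``is_bridge``: z-betweenness >= threshold. ``is_highly_central``: both
    z-strength and z-closeness >= threshold. Purely descriptive cut-offs — no
    hypothesis test is attached.
    """
    if profile.z_betweenness is None:
        raise ValidationError("profile must be z-standardized before classification")
    profile.is_bridge = profile.z_betweenness >= threshold
    profile.is_highly_central = (profile.z_strength >= threshold) & (
        profile.z_closeness >= threshold
    )
    return profile


def characterize_communities(nets, threshold: float = 2.0) -> list:
    """Full centrality characterization of a set of community networks.

    Computes raw betweenness/strength/closeness per network, z-standardizes
    each statistic across all supplied networks, and classifies bridge and
    highly-central symptoms at the given threshold (default 2 SD).
    """
    nets = list(nets)
    if not nets:
        raise ValidationError("need at least one community network")
    profiles = [
        CentralityProfile(
            community_id=net.community_id,
            symptom_labels=net.symptom_labels,
            betweenness=betweenness(net),
            strength=strength(net),
            closeness=closeness(net),
        )
        for net in nets
    ]
    for stat in ("betweenness", "strength", "closeness"):
        zs = z_standardize([getattr(p, stat) for p in profiles])
        for p, z in zip(profiles, zs):
            setattr(p, f"z_{stat}", z)
    for p in profiles:
        classify_symptoms(p, threshold)
    return profiles


def detect_symptom_clusters(
    net: CommunityConcordanceNetwork, steps: int = 4, seed: int | None = None
) -> SymptomClusterSolution:
    """Walktrap symptom clusters on the normalized community network."""
    partition = walktrap_communities(
        WeightedGraph(net.symptom_labels, net.normalized_weights), steps=steps, seed=seed
    )
    return SymptomClusterSolution(
        community_id=net.community_id,
        symptom_labels=net.symptom_labels,
        labels=partition.labels,
        modularity=partition.modularity,
    )


def centrality_table(profiles) -> pd.DataFrame:
    """Tidy per-(community, symptom) table of all centralities and flags."""
    rows = []
    for p in profiles:
        for i, s in enumerate(p.symptom_labels):
            rows.append(
                {
                    "community_id": p.community_id,
                    "symptom": s,
                    "betweenness": p.betweenness[i],
                    "strength": p.strength[i],
                    "closeness": p.closeness[i],
                    "z_betweenness": p.z_betweenness[i],
                    "z_strength": p.z_strength[i],
                    "z_closeness": p.z_closeness[i],
                    "is_bridge": bool(p.is_bridge[i]),
                    "is_highly_central": bool(p.is_highly_central[i]),
                }
            )
    return pd.DataFrame(rows)
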
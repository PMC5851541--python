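import itertools

import igraph as ig
import numpy as np
import pytest

from concordnet import (
    CommunityPartition,
    SimilarityMatrix,
    ValidationError,
    WeightedGraph,
    modularity,
    similarity_to_graph,
    walktrap_communities,
)
from _oracles import max_modularity_exhaustive, modularity_direct
from conftest import random_weighted_graph


def clique_pair_weights(size=4, bridge=0.1):
    """Two unit-weight cliques joined by one weak edge."""
    n = 2 * size
    w = np.zeros((n, n))
    for a, b in itertools.combinations(range(size), 2):
        w[a, b] = w[b, a] = 1.0
        w[a + size, b + size] = w[b + size, a + size] = 1.0
    w[0, size] = w[size, 0] = bridge
    return w


def labelled(w):
    return WeightedGraph(tuple(f"n{i}" for i in range(len(w))), w)


class TestWeightedGraph:
    def test_negative_weight_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValidationError):
            labelled(w)

    def test_self_loop_rejected(self):
        w = np.array([[1.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            labelled(w)

    def test_asymmetric_rejected(self):
        w = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValidationError):
            labelled(w)


class TestModularity:
    def test_single_community_is_exactly_zero(self, rng):
        w = random_weighted_graph(rng, 7)
        assert modularity(labelled(w), np.zeros(7, dtype=int)) == pytest.approx(0.0, abs=1e-15)

    def test_two_equal_disconnected_cliques_score_half(self):
        w = clique_pair_weights(bridge=0.0)
        labels = np.array([0] * 4 + [1] * 4)
        assert modularity(labelled(w), labels) == pytest.approx(0.5)

    def test_matches_literal_double_sum_on_random_graphs(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 6)
            labels = rng.integers(0, 3, 6)
            assert modularity(labelled(w), labels) == pytest.approx(
                modularity_direct(w, labels), abs=1e-12
            )

    def test_invariant_under_relabeling_and_node_permutation(self, rng):
        w = random_weighted_graph(rng, 8)
        labels = rng.integers(0, 3, 8)
        q = modularity(labelled(w), labels)
        assert modularity(labelled(w), 10 - labels) == pytest.approx(q)
        perm = rng.permutation(8)
        assert modularity(
            labelled(w[np.ix_(perm, perm)]), labels[perm]
        ) == pytest.approx(q)

    def test_zero_weight_graph_defined_as_zero(self):
        assert modularity(labelled(np.zeros((3, 3))), [0, 1, 2]) == 0.0

    def test_matches_igraph_on_random_graphs(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, 7)
            labels = rng.integers(0, 3, 7)
            g = labelled(w)
            edges = [(i, j) for i, j, _ in g.edges()]
            igr = ig.Graph(edges, n=7)
            igr.es["weight"] = [wt for _, _, wt in g.edges()]
            expected = igr.modularity(labels.tolist(), weights="weight")
            assert modularity(g, labels) == pytest.approx(expected, abs=1e-12)


class TestWalktrap:
    def test_disconnected_triangles_split_into_components(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        part = walktrap_communities(labelled(w))
        assert part.n_communities == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1

    def test_two_cliques_with_weak_bridge_recover_exhaustive_optimum(self):
        w = clique_pair_weights()
        part = walktrap_communities(labelled(w))
        best_q, best_labels = max_modularity_exhaustive(w)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        assert part.labels.tolist() == [0] * 4 + [1] * 4

    def test_uniform_complete_graph_is_one_community(self):
        w = np.ones((6, 6)) - np.eye(6)
        part = walktrap_communities(labelled(w))
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-15)

    def test_isolates_become_singletons(self):
        w = np.zeros((5, 5))
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            w[a, b] = w[b, a] = 1.0
        part = walktrap_communities(labelled(w))
        assert part.labels[3] != part.labels[4]
        assert {part.labels[3], part.labels[4]} & {part.labels[0]} == set()

    def test_edgeless_graph_gives_all_singletons(self):
        part = walktrap_communities(labelled(np.zeros((4, 4))))
        assert part.n_communities == 4 and part.modularity == 0.0

    def test_deterministic_across_runs(self, rng):
        w = random_weighted_graph(rng, 12)
        g = labelled(w)
        first = walktrap_communities(g, seed=1)
        second = walktrap_communities(g, seed=999)
        assert np.array_equal(first.labels, second.labels)
        assert first.modularity == second.modularity

    def test_reported_modularity_consistent_with_modularity_function(self, rng):
        w = random_weighted_graph(rng, 10)
        g = labelled(w)
        part = walktrap_communities(g)
        assert part.modularity == pytest.approx(modularity(g, part.labels))

    def test_never_beats_exhaustive_search(self, rng):
        for _ in range(5):
            w = random_weighted_graph(rng, 6)
            part = walktrap_communities(labelled(w))
            best_q, _ = max_modularity_exhaustive(w)
            assert part.modularity <= best_q + 1e-12


class TestSimilarityToGraph:
    def test_zero_pairs_have_no_edge(self):
        values = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]])
        g = similarity_to_graph(SimilarityMatrix(("a", "b", "c"), values))
        assert len(list(g.edges())) == 2
        assert np.allclose(np.diagonal(g.weights), 0.0)

    def test_identity_similarity_gives_edgeless_graph(self):
        g = similarity_to_graph(SimilarityMatrix(("a", "b", "c"), np.eye(3)))
        assert list(g.edges()) == []

    def test_weights_stay_symmetric(self, rng):
        v = random_weighted_graph(rng, 5) / 2
        np.fill_diagonal(v, 1.0)
        g = similarity_to_graph(SimilarityMatrix(tuple("abcde"), v))
        assert np.allclose(g.weights, g.weights.T)


class TestCommunityPartition:
    def test_labels_must_be_contiguous(self):
        with pytest.raises(ValidationError):
            CommunityPartition(np.array([0, 2, 2]), 0.0, 2)

    def test_sizes_and_members(self):
        part = CommunityPartition(np.array([0, 1, 0, 1, 1]), 0.0, 2)
        assert part.sizes().tolist() == [2, 3]
        assert part.members(1).tolist() == [1, 3, 4]
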
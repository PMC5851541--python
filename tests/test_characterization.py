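import numpy as np
import pytest

from concordnet import (
    CommunityConcordanceNetwork,
    betweenness,
    characterize_communities,
    classify_symptoms,
    closeness,
    detect_symptom_clusters,
    shortest_path_distances,
    strength,
    z_standardize,
)
from concordnet.characterization import CentralityProfile
from _oracles import betweenness_exhaustive, closeness_exhaustive, geodesics_exhaustive


def network_from_weights(w, community_id=0):
    w = np.asarray(w, dtype=float)
    k = len(w)
    counts = (w.sum(axis=1) > 0).astype(int)  # placeholder endorsements
    return CommunityConcordanceNetwork(
        tuple(f"s{i}" for i in range(k)), counts, w, community_id, n_patients=1
    )


def path_network(w12=1.0, w23=1.0):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[1, 2] = w[2, 1] = w23
    return network_from_weights(w)


def random_network(rng, k, density=0.7):
    w = rng.random((k, k)) * (rng.random((k, k)) < density)
    w = np.triu(w, 1)
    return network_from_weights(w + w.T)


class TestStrength:
    def test_isolate_scores_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        assert strength(network_from_weights(w))[2] == 0.0

    def test_direct_sum_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        assert strength(network_from_weights(w))[0] == pytest.approx(1.5)

    def test_handshake_lemma(self, rng):
        net = random_network(rng, 8)
        total_edge_weight = net.normalized_weights.sum() / 2
        assert strength(net).sum() == pytest.approx(2 * total_edge_weight)

    def test_adding_an_edge_never_decreases_strength(self, rng):
        net = random_network(rng, 6)
        w = net.normalized_weights.copy()
        zero_pairs = [(i, j) for i in range(6) for j in range(i + 1, 6) if w[i, j] == 0]
        if not zero_pairs:
            w[0, 1] = w[1, 0] = 0.0
            zero_pairs = [(0, 1)]
        i, j = zero_pairs[0]
        before = strength(network_from_weights(w))
        w[i, j] = w[j, i] = 0.5
        after = strength(network_from_weights(w))
        assert (after >= before - 1e-15).all()


class TestShortestPaths:
    def test_two_hop_chain_distance_adds_inverse_weights(self):
        net = path_network(0.5, 0.5)
        d = shortest_path_distances(net)
        assert d[0, 2] == pytest.approx(4.0)  # 2 + 2

    def test_direct_edge_beats_two_hop_route(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        d = shortest_path_distances(network_from_weights(w))
        assert d[0, 2] == pytest.approx(1.0)

    def test_unreachable_pairs_are_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_path_distances(network_from_weights(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[2, 1])

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(10):
            net = random_network(rng, 6)
            expected, _ = geodesics_exhaustive(net.normalized_weights)
            assert np.allclose(shortest_path_distances(net), expected)


class TestBetweenness:
    def test_chain_middle_carries_the_single_geodesic(self):
        b = betweenness(path_network())
        assert b.tolist() == [0.0, 1.0, 0.0]

    def test_star_center_carries_all_leaf_pairs(self):
        w = np.zeros((4, 4))
        for leaf in (1, 2, 3):
            w[0, leaf] = w[leaf, 0] = 1.0
        b = betweenness(network_from_weights(w))
        assert b[0] == pytest.approx(3.0)  # C(3,2) leaf pairs
        assert np.allclose(b[1:], 0.0)

    def test_matches_exhaustive_geodesic_counting(self, rng):
        for _ in range(10):
            net = random_network(rng, 6)
            assert np.allclose(
                betweenness(net),
                betweenness_exhaustive(net.normalized_weights),
                atol=1e-9,
            )

    def test_sole_connector_attains_maximum_betweenness(self):
        # two dense blocks joined only through node 4
        k = 9
        w = np.zeros((k, k))
        for block in (range(0, 4), range(5, 9)):
            for i in block:
                for j in block:
                    if i < j:
                        w[i, j] = w[j, i] = 0.9
        for i in list(range(0, 4)) + list(range(5, 9)):
            w[i, 4] = w[4, i] = 0.6
        b = betweenness(network_from_weights(w))
        assert b.argmax() == 4


class TestCloseness:
    def test_unit_chain_hand_values(self):
        c = closeness(path_network())
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(2 / 3)

    def test_isolate_scores_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert closeness(network_from_weights(w))[2] == 0.0

    def test_uniform_complete_network_scores_one_everywhere(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert np.allclose(closeness(network_from_weights(w)), 1.0)

    def test_matches_exhaustive_oracle_including_disconnected(self, rng):
        for _ in range(10):
            net = random_network(rng, 6, density=0.5)
            assert np.allclose(
                closeness(net),
                closeness_exhaustive(net.normalized_weights),
                atol=1e-9,
            )


class TestZStandardize:
    def test_pooled_mean_zero_sd_one(self, rng):
        profiles = [rng.random(5), rng.random(7), rng.random(3)]
        zs = z_standardize(profiles)
        pooled = np.concatenate(zs)
        assert pooled.mean() == pytest.approx(0.0, abs=1e-10)
        assert pooled.std() == pytest.approx(1.0, abs=1e-10)

    def test_single_community_hand_example(self):
        (z,) = z_standardize([np.array([0.0, 0.0, 10.0])])
        assert z[2] == pytest.approx(np.sqrt(2))  # population-SD convention

    def test_constant_statistic_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            zs = z_standardize([np.full(4, 3.3), np.full(2, 3.3)])
        assert all((z == 0).all() for z in zs)


class TestClassification:
    def make_profile(self, z_b, z_s, z_c):
        k = len(z_b)
        return CentralityProfile(
            community_id=0,
            symptom_labels=tuple(f"s{i}" for i in range(k)),
            betweenness=np.zeros(k),
            strength=np.zeros(k),
            closeness=np.zeros(k),
            z_betweenness=np.array(z_b, dtype=float),
            z_strength=np.array(z_s, dtype=float),
            z_closeness=np.array(z_c, dtype=float),
        )

    def test_bridge_rule_at_two_sd(self):
        profile = self.make_profile([4.3, 1.9, 2.0], [0, 0, 0], [0, 0, 0])
        classify_symptoms(profile)
        assert profile.is_bridge.tolist() == [True, False, True]

    def test_highly_central_requires_both_strength_and_closeness(self):
        profile = self.make_profile([0, 0], [2.5, 2.5], [1.0, 2.1])
        classify_symptoms(profile)
        assert profile.is_highly_central.tolist() == [False, True]

    def test_threshold_is_configurable(self):
        profile = self.make_profile([1.5], [0], [0])
        classify_symptoms(profile, threshold=1.0)
        assert profile.is_bridge.tolist() == [True]


class TestSymptomClusters:
    def test_two_disconnected_blocks_give_two_clusters(self):
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i < j:
                        w[i, j] = w[j, i] = 0.8
        sol = detect_symptom_clusters(network_from_weights(w))
        assert sol.n_clusters == 2

    def test_uniform_complete_network_is_one_cluster(self):
        w = 0.5 * (np.ones((5, 5)) - np.eye(5))
        sol = detect_symptom_clusters(network_from_weights(w))
        assert sol.n_clusters == 1
        assert sol.modularity == pytest.approx(0.0, abs=1e-15)

    def test_planted_blocks_with_weak_bridge_recovered(self):
        w = np.zeros((7, 7))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i < j:
                        w[i, j] = w[j, i] = 0.9
        # symptom 6 weakly bridges the blocks
        w[0, 6] = w[6, 0] = 0.1
        w[3, 6] = w[6, 3] = 0.1
        sol = detect_symptom_clusters(network_from_weights(w))
        labels = sol.labels
        assert len(set(labels[:3].tolist())) == 1
        assert len(set(labels[3:6].tolist())) == 1
        assert labels[0] != labels[3]


class TestCharacterizeCommunities:
    def test_end_to_end_bridge_detection_across_two_networks(self):
        # community 0: two blocks bridged by symptom 4; community 1: uniform
        k = 9
        w0 = np.zeros((k, k))
        for block in (range(0, 4), range(5, 9)):
            for i in block:
                for j in block:
                    if i < j:
                        w0[i, j] = w0[j, i] = 0.9
        for i in list(range(0, 4)) + list(range(5, 9)):
            w0[i, 4] = w0[4, i] = 0.6
        w1 = 0.5 * (np.ones((k, k)) - np.eye(k))
        nets = [network_from_weights(w0, 0), network_from_weights(w1, 1)]
        profiles = characterize_communities(nets)
        by_id = {p.community_id: p for p in profiles}
        assert by_id[0].bridge_symptoms() == ["s4"]
        assert by_id[1].bridge_symptoms() == []
        pooled = np.concatenate([p.z_betweenness for p in profiles])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-10)
        assert pooled.std() == pytest.approx(1.0, abs=1e-10)
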
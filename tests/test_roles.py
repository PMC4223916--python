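"""Flow-role detection, role profiles, role mixes and organigram clustering."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from flowscope import (
    DEFAULT_ROLE_GAMMA,
    Partition,
    PlantedRoleSpec,
    RoleAssignment,
    RoleMix,
    build_feature_matrix,
    cluster_role_mixes,
    cosine_similarity,
    detect_roles,
    generate_role_planted,
    retweet_cdf_table,
    rmst,
    role_flow_profiles,
    role_mix,
    similarity_to_distance,
    toy,
)


def _role_graph(net, gamma=DEFAULT_ROLE_GAMMA):
    Y = cosine_similarity(build_feature_matrix(net))
    return rmst(similarity_to_distance(Y), gamma=gamma, similarity=Y)


class TestDetectRoles:
    def test_directed_cycle_has_one_role(self):
        # all nodes automorphic -> identical features -> single role
        net = toy("cycle", 8)
        assignment = detect_roles(_role_graph(net), net, seed=0)
        assert assignment.n_roles == 1

    def test_planted_three_roles_recovered(self):
        net, truth = generate_role_planted(PlantedRoleSpec(seed=1))
        assignment = detect_roles(_role_graph(net), net, seed=11)
        ari = adjusted_rand_score(
            truth.labels,
            assignment.as_partition().aligned_labels(truth.node_labels),
        )
        assert assignment.n_roles == 3
        assert ari >= 0.9

    def test_roles_ordered_by_in_strength(self):
        net, _ = generate_role_planted(PlantedRoleSpec(seed=1))
        assignment = detect_roles(_role_graph(net), net, seed=11)
        in_s = net.in_strength
        means = [in_s[assignment.labels == r].mean()
                 for r in range(assignment.n_roles)]
        assert means == sorted(means, reverse=True)

    def test_node_set_mismatch_rejected(self):
        net = toy("cycle", 5)
        other = toy("cycle", 6)
        with pytest.raises(ValueError):
            detect_roles(_role_graph(net), other)


class TestRoleFlowProfiles:
    def test_single_role_profile_is_global_column_mean(self):
        net = toy("cycle", 6)
        Xf = build_feature_matrix(net, k_max=4)
        roles = RoleAssignment(net.node_labels, np.zeros(6, dtype=int), n_roles=1)
        prof = role_flow_profiles(roles, Xf)
        raw = np.log1p(Xf.unscaled())
        for _, row in prof.iterrows():
            col = int(row["length"]) - 1
            col += 0 if row["direction"] == "in" else Xf.k_max
            assert row["mean_log1p"] == pytest.approx(raw[:, col].mean())

    def test_sources_dominate_incoming_sinks_dominate_outgoing(self):
        net, truth = generate_role_planted(PlantedRoleSpec(seed=2))
        Xf = build_feature_matrix(net)
        prof = role_flow_profiles(truth, Xf)
        # planted role 0 = references (sources of content, sinks of the
        # attention walk), role 2 = listeners
        by = prof.set_index(["role", "direction", "length"])["mean_log1p"]
        for k in range(1, Xf.k_max + 1):
            assert by[(0, "in", k)] >= by[(2, "in", k)]
            assert by[(2, "out", k)] >= by[(0, "out", k)]

    def test_permutation_invariant(self):
        net, truth = generate_role_planted(PlantedRoleSpec(seed=3))
        Xf = build_feature_matrix(net)
        prof1 = role_flow_profiles(truth, Xf)
        rng = np.random.default_rng(0)
        perm = rng.permutation(net.N)
        shuffled = RoleAssignment(
            tuple(truth.node_labels[i] for i in perm),
            truth.labels[perm],
            n_roles=truth.n_roles,
        )
        prof2 = role_flow_profiles(shuffled, Xf)
        pd.testing.assert_frame_equal(prof1, prof2)


class TestRoleMix:
    def test_single_member_community_is_unit_vector(self):
        nodes = ("a", "b", "c")
        part = Partition(nodes, [0, 1, 1])
        roles = RoleAssignment(nodes, np.array([2, 0, 1]), n_roles=3)
        mix = role_mix(part, roles)
        np.testing.assert_allclose(mix.fractions[0], [0, 0, 1])

    def test_balanced_community_mix(self):
        nodes = tuple("abcd")
        part = Partition(nodes, [0, 0, 0, 0])
        roles = RoleAssignment(nodes, np.array([0, 0, 1, 1]), n_roles=2)
        mix = role_mix(part, roles)
        np.testing.assert_allclose(mix.fractions[0], [0.5, 0.5])

    def test_matches_naive_counting_and_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        nodes = tuple(f"n{i}" for i in range(40))
        part = Partition(nodes, rng.integers(0, 5, 40))
        roles = RoleAssignment(nodes, rng.integers(0, 3, 40), n_roles=3)
        mix = role_mix(part, roles)
        np.testing.assert_allclose(mix.fractions.sum(axis=1), 1.0, atol=1e-12)
        for c in range(part.k):
            members = [n for n, lab in zip(nodes, part.labels) if lab == c]
            for r in range(3):
                count = sum(roles.assignment[n] == r for n in members)
                assert mix.fractions[c, r] == count / len(members)

    def test_node_set_mismatch_rejected(self):
        part = Partition(("a", "b"), [0, 1])
        roles = RoleAssignment(("a", "c"), np.array([0, 1]), n_roles=2)
        with pytest.raises(ValueError):
            role_mix(part, roles)


class TestClusterRoleMixes:
    def _mix(self, fractions):
        fractions = np.asarray(fractions, dtype=float)
        return RoleMix(
            communities=tuple(range(len(fractions))),
            fractions=fractions,
            counts=fractions * 10,
            n_roles=fractions.shape[1],
        )

    def test_two_point_clouds_split_perfectly(self):
        rng = np.random.default_rng(1)
        a = np.clip(np.array([1.0, 0, 0]) + rng.normal(0, 0.02, (6, 3)), 0, 1)
        b = np.clip(np.array([0, 0, 1.0]) + rng.normal(0, 0.02, (6, 3)), 0, 1)
        org = cluster_role_mixes(self._mix(np.vstack([a, b])), k=2, seed=0)
        labels = org.labels
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_auto_selects_two_for_two_clouds(self):
        rng = np.random.default_rng(2)
        a = np.clip(np.array([0.9, 0.1]) + rng.normal(0, 0.01, (8, 2)), 0, 1)
        b = np.clip(np.array([0.1, 0.9]) + rng.normal(0, 0.01, (8, 2)), 0, 1)
        org = cluster_role_mixes(self._mix(np.vstack([a, b])), k="auto", seed=3)
        assert org.k == 2
        assert org.scores  # silhouette diagnostics recorded

    def test_identical_mixes_degenerate_to_one_cluster(self):
        org = cluster_role_mixes(self._mix(np.tile([0.5, 0.5], (5, 1))),
                                 k="auto", seed=0)
        assert org.degenerate
        assert org.k == 1

    def test_k_not_smaller_than_community_count_rejected(self):
        with pytest.raises(ValueError):
            cluster_role_mixes(self._mix(np.eye(3)), k=3, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(3), size=12)
        m = self._mix(X)
        o1 = cluster_role_mixes(m, k=3, seed=9)
        o2 = cluster_role_mixes(m, k=3, seed=9)
        np.testing.assert_array_equal(o1.labels, o2.labels)


class TestRetweetHook:
    def test_cdf_reaches_one_per_role(self):
        nodes = tuple("abcdef")
        roles = RoleAssignment(nodes, np.array([0, 0, 0, 1, 1, 1]), n_roles=2)
        counts = {"a": 5, "b": 1, "c": 3, "d": 10, "e": 2, "f": 7}
        table = retweet_cdf_table(roles, counts)
        for r in (0, 1):
            sub = table[table["role"] == r]
            assert sub["cdf"].iloc[-1] == 1.0
            assert sub["value"].is_monotonic_increasing
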
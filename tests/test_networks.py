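"""Network construction, hierarchy roles, tier-ratio tests, relatedness."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import hawkdove as hd
from hawkdove.decision import FIB_MARK, PHI
from hawkdove.networks import (
    InteractionNetwork,
    RoleAssignment,
    all_pairs_descriptors,
    assign_directional_roles,
    assign_mutualism_hierarchy,
    build_networks,
    compare_core_periphery_trait,
    ibs_matrix,
    network_correlation,
    relatedness_network,
    tier_mass_ratio,
)


class TestBuildNetworks:
    def test_complete_graph_weights_match_brute_force(self):
        """q=1 on 4 masses: 6 edges per network, hand-checkable weights."""
        traits = pd.Series({"a": 10.0, "b": 6.2, "c": 3.8, "d": 2.0})
        nets = build_networks(traits, retention=1.0)
        for net in nets.values():
            assert net.graph.number_of_edges() == 6
        for u, v in itertools.combinations(traits.index, 2):
            x, y = max(traits[u], traits[v]), min(traits[u], traits[v])
            g = nets["mutualism"].graph
            assert g[u][v]["weight"] == pytest.approx(x * y / (x - y))
            ga = nets["aggression"].graph
            src = u if traits[u] > traits[v] else v
            dst = v if src == u else u
            assert ga[src][dst]["weight"] == pytest.approx(x / y)

    @pytest.mark.parametrize("q", [1.0, 0.5, 0.25, 0.1])
    def test_retention_contract(self, q, toy_traits):
        nets = build_networks(toy_traits, retention=q)
        m = len(toy_traits) * (len(toy_traits) - 1) // 2
        for net in nets.values():
            assert net.graph.number_of_edges() == round(q * m)
            assert net.sparsity == q

    def test_directed_edges_point_from_heavier(self, toy_traits):
        nets = build_networks(toy_traits, retention=1.0)
        for t in ("aggression", "altruism"):
            for u, v in nets[t].graph.edges():
                assert toy_traits[u] > toy_traits[v]

    def test_retention_deterministic_and_ranked(self, toy_traits):
        a = build_networks(toy_traits, retention=0.4)["mutualism"]
        b = build_networks(toy_traits, retention=0.4)["mutualism"]
        assert set(a.graph.edges()) == set(b.graph.edges())
        kept = {frozenset(e) for e in a.graph.edges()}
        wmin = min(d["weight"] for _, _, d in a.graph.edges(data=True))
        for (i, j), val in a.all_pairs.items():
            if frozenset((i, j)) not in kept:
                assert val <= wmin

    def test_bad_retention_rejected(self, toy_traits):
        for q in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                build_networks(toy_traits, retention=q)

    def test_degenerate_dyads_skipped_with_warning(self):
        traits = pd.Series({"a": 5.0, "b": 5.0, "c": 2.0, "d": 1.0})
        with pytest.warns(UserWarning, match="degenerate"):
            nets = build_networks(traits, retention=1.0, on_degenerate="skip")
        assert nets["mutualism"].graph.number_of_edges() == 5  # 6 dyads - 1 tie

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            build_networks(pd.Series({"a": 2.0, "b": 1.0}))


def _net(edges, net_type="mutualism", nodes=()):
    g = nx.DiGraph() if net_type in ("aggression", "altruism") else nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return InteractionNetwork(net_type, g, 1.0, pd.Series(dtype=float))


class TestMutualismHierarchy:
    def test_star_graph(self):
        net = _net([("hub", f"l{i}") for i in range(6)])
        roles = assign_mutualism_hierarchy(net).roles
        assert roles["hub"] == "primary_leader"
        assert all(roles[f"l{i}"] == "secondary_leader" for i in range(6))

    def test_chain_below_hub(self):
        """Hub with inflated degree, then a path hub-s-t-f: roles walk
        primary -> secondary -> tertiary -> follower."""
        edges = [("hub", f"x{i}") for i in range(5)] + [
            ("hub", "s"), ("s", "t"), ("t", "f")]
        roles = assign_mutualism_hierarchy(_net(edges)).roles
        assert roles["hub"] == "primary_leader"
        assert roles["s"] == "secondary_leader"
        assert roles["t"] == "tertiary_leader"
        assert roles["f"] == "follower"

    def test_regular_graph_has_no_primary(self):
        net = _net([(i, (i + 1) % 6) for i in range(6)])  # 6-cycle, all degree 2
        with pytest.warns(UserWarning, match="no primary leaders"):
            roles = assign_mutualism_hierarchy(net).roles
        assert set(roles.values()) == {"unassigned"}

    def test_partition_disjoint_exhaustive(self, small_cohort):
        traits = small_cohort.set_index("id")["trait"]
        net = build_networks(traits, retention=0.3)["mutualism"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra = assign_mutualism_hierarchy(net)
        assert set(ra.roles) == set(net.graph.nodes)
        valid = {"primary_leader", "secondary_leader", "tertiary_leader",
                 "follower", "unassigned"}
        assert set(ra.roles.values()) <= valid

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            assign_mutualism_hierarchy(_net([]))

    def test_wrong_type_rejected(self):
        with pytest.raises(ValueError):
            assign_mutualism_hierarchy(_net([("a", "b")], net_type="aggression"))


class TestDirectionalRoles:
    def test_pure_actor_and_recipients(self):
        roles = assign_directional_roles(
            _net([("A", "B"), ("A", "C")], "aggression")).roles
        assert roles == {"A": "hawk", "B": "dove", "C": "dove"}

    def test_mixed_role(self):
        roles = assign_directional_roles(
            _net([("A", "B"), ("B", "C")], "aggression")).roles
        assert roles["B"] == "hawk_dove"

    def test_altruism_labels_and_isolated(self):
        roles = assign_directional_roles(
            _net([("A", "B"), ("B", "C")], "altruism", nodes=["D"])).roles
        assert roles == {"A": "altruist", "B": "altruist_egoist",
                         "C": "egoist", "D": "isolated"}

    def test_six_node_enumeration(self):
        edges = [("a", "d"), ("a", "e"), ("b", "e"), ("e", "f")]
        roles = assign_directional_roles(_net(edges, "aggression", nodes="abcdef")).roles
        expected = {"a": "hawk", "b": "hawk", "c": "isolated",
                    "d": "dove", "e": "hawk_dove", "f": "dove"}
        assert roles == expected


class TestTierRatio:
    def test_hand_arithmetic(self):
        ra = RoleAssignment.from_labels(
            "mutualism",
            {"u": "primary_leader", "l1": "secondary_leader", "l2": "secondary_leader"},
        )
        res = tier_mass_ratio(ra, {"u": 10.0, "l1": 6.2, "l2": 8.2},
                              ("secondary_leader", "primary_leader"))
        assert sorted(res.ratios) == pytest.approx([0.62, 0.82])
        assert res.mean_ratio == pytest.approx(0.72)

    def test_all_at_threshold_gives_zero_statistic(self):
        ra = RoleAssignment.from_labels(
            "mutualism", {"u": "primary_leader", "l1": "secondary_leader",
                          "l2": "secondary_leader"})
        traits = {"u": 10.0, "l1": 10.0 * PHI, "l2": 10.0 * PHI}
        res = tier_mass_ratio(ra, traits, ("secondary_leader", "primary_leader"),
                              threshold=10.0 * PHI / 10.0)
        assert res.statistic == 0.0
        assert res.mean_ratio == pytest.approx(PHI)

    def test_planted_band_rejects_phi(self):
        """Secondary/primary ratios ~ N(0.75, 0.05): mean <= phi rejected
        at alpha = 0.001 (the qualitative hierarchy finding)."""
        rng = np.random.default_rng(42)
        upper = {f"p{i}": 100.0 for i in range(3)}
        lower = {f"s{i}": 100.0 * rng.normal(0.75, 0.05) for i in range(20)}
        labels = {**{k: "primary_leader" for k in upper},
                  **{k: "secondary_leader" for k in lower}}
        ra = RoleAssignment.from_labels("mutualism", labels)
        res = tier_mass_ratio(ra, {**upper, **lower},
                              ("secondary_leader", "primary_leader"),
                              threshold=PHI, alternative="greater")
        assert res.p < 0.001
        assert res.direction == "above"

    def test_connected_dyads_only_when_graph_present(self):
        g = nx.Graph([("u", "l1")])
        g.add_node("l2")
        ra = RoleAssignment(
            "mutualism",
            {"u": "primary_leader", "l1": "secondary_leader", "l2": "secondary_leader"},
            graph=g,
        )
        res = tier_mass_ratio(ra, {"u": 10.0, "l1": 6.2, "l2": 8.2},
                              ("secondary_leader", "primary_leader"))
        assert res.ratios == pytest.approx([0.62])

    def test_permutation_p_seeded(self):
        rng = np.random.default_rng(0)
        traits = {f"p{i}": 100.0 for i in range(4)}
        traits.update({f"s{i}": 60.0 + rng.normal(0, 2) for i in range(8)})
        labels = {k: ("primary_leader" if k.startswith("p") else "secondary_leader")
                  for k in traits}
        ra = RoleAssignment.from_labels("mutualism", labels)
        r1 = tier_mass_ratio(ra, traits, ("secondary_leader", "primary_leader"),
                             n_permutations=200, seed=5)
        r2 = tier_mass_ratio(ra, traits, ("secondary_leader", "primary_leader"),
                             n_permutations=200, seed=5)
        assert r1.p_perm == r2.p_perm
        assert 0 < r1.p_perm <= 1

    def test_empty_tier_named_in_error(self):
        ra = RoleAssignment.from_labels("mutualism", {"u": "primary_leader"})
        with pytest.raises(ValueError, match="secondary_leader"):
            tier_mass_ratio(ra, {"u": 1.0}, ("secondary_leader", "primary_leader"))


class TestRelatedness:
    def test_ibs_extremes(self):
        geno = pd.DataFrame([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2]],
                            index=["i", "j", "k"])
        sim = ibs_matrix(geno)
        assert sim.loc["i", "j"] == pytest.approx(1.0)
        # i vs k: opposite homozygotes at 3 SNPs, equal het at 1
        assert sim.loc["i", "k"] == pytest.approx((0 + 1 + 0 + 0) / 4)

    def test_opposite_homozygotes_everywhere(self):
        geno = pd.DataFrame([[0] * 5, [2] * 5], index=["i", "j"])
        assert ibs_matrix(geno).loc["i", "j"] == pytest.approx(0.0)

    def test_fullsib_ibs_in_mendelian_band(self):
        geno = hd.generate_fullsib_genotypes(30, 1000, seed=8)
        net, roles = relatedness_network(geno, retention=0.1)
        vals = net.all_pairs.to_numpy()
        assert 0.5 < vals.mean() < 0.9
        assert vals.mean() == pytest.approx(hd.expected_ibs(), abs=0.02)
        assert set(roles.roles.values()) <= {"core", "periphery"}

    def test_input_guards(self):
        with pytest.raises(ValueError, match="50 SNPs"):
            relatedness_network(hd.generate_fullsib_genotypes(5, 10, seed=0))
        with pytest.raises(ValueError, match="3 individuals"):
            relatedness_network(hd.generate_fullsib_genotypes(2, 100, seed=0))


class TestNetworkCorrelation:
    def test_self_correlation_is_one(self, toy_traits):
        nets = build_networks(toy_traits, retention=0.5)
        r, p = network_correlation(nets["mutualism"], nets["mutualism"])
        assert r == pytest.approx(1.0)

    def test_symmetry(self, toy_traits):
        nets = build_networks(toy_traits, retention=0.5)
        r_ab, _ = network_correlation(nets["mutualism"], nets["antagonism"])
        r_ba, _ = network_correlation(nets["antagonism"], nets["mutualism"])
        assert r_ab == pytest.approx(r_ba)

    def test_matches_hand_computation(self, toy_traits):
        table = all_pairs_descriptors(toy_traits)
        expected = np.corrcoef(table["z_mu"], table["z_an"])[0, 1]
        nets = build_networks(toy_traits, retention=1.0)
        r, _ = network_correlation(nets["mutualism"], nets["antagonism"])
        assert r == pytest.approx(expected, rel=1e-12)

    def test_aggression_altruism_positive(self, toy_traits):
        """z_ag = x/y and z_al = 1 - y/x both grow with size disparity."""
        nets = build_networks(toy_traits, retention=1.0)
        r, _ = network_correlation(nets["aggression"], nets["altruism"])
        assert r > 0

    def test_zero_variance_undefined(self):
        idx = pd.MultiIndex.from_tuples([("a", "b"), ("a", "c"), ("b", "c")])
        flat = InteractionNetwork("mutualism", nx.Graph(), 1.0,
                                  pd.Series([1.0, 1.0, 1.0], index=idx))
        other = InteractionNetwork("antagonism", nx.Graph(), 1.0,
                                   pd.Series([1.0, 2.0, 3.0], index=idx))
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = network_correlation(flat, other)
        assert np.isnan(r)


class TestCorePeriphery:
    def test_identical_groups_p_one(self):
        ra = RoleAssignment.from_labels(
            "relatedness",
            {"a": "core", "b": "core", "c": "periphery", "d": "periphery"})
        out = compare_core_periphery_trait(ra, {"a": 5.0, "b": 6.0, "c": 5.0, "d": 6.0})
        assert out["p"] == pytest.approx(1.0)

    def test_disjoint_support_tiny_p(self):
        labels = {f"c{i}": "core" for i in range(8)}
        labels.update({f"p{i}": "periphery" for i in range(8)})
        traits = {f"c{i}": 100.0 + i for i in range(8)}
        traits.update({f"p{i}": 1.0 + 0.1 * i for i in range(8)})
        out = compare_core_periphery_trait(
            RoleAssignment.from_labels("relatedness", labels), traits)
        assert out["p"] < 1e-6

    def test_type_one_error_calibrated(self):
        """Same-distribution groups: rejection rate ~ alpha over many cohorts."""
        rng = np.random.default_rng(77)
        alpha, rejections, n_sim = 0.05, 0, 400
        for _ in range(n_sim):
            traits = {f"i{k}": rng.lognormal(0, 0.3) for k in range(20)}
            labels = {k: ("core" if i < 6 else "periphery")
                      for i, k in enumerate(traits)}
            out = compare_core_periphery_trait(
                RoleAssignment.from_labels("relatedness", labels), traits)
            rejections += out["p"] < alpha
        assert rejections / n_sim == pytest.approx(alpha, abs=0.03)

    def test_small_group_rejected(self):
        ra = RoleAssignment.from_labels("relatedness", {"a": "core", "b": "periphery",
                                                        "c": "periphery"})
        with pytest.raises(ValueError):
            compare_core_periphery_trait(ra, {"a": 1.0, "b": 2.0, "c": 3.0})


def test_hypothesis_one_qualitative_split():
    """A cohort planted so mutualism-tier ratios sit above phi and
    aggression-tier ratios below phi reproduces the qualitative split."""
    rng = np.random.default_rng(13)
    prim = {f"p{i}": 1000.0 * (1 + 0.02 * i) for i in range(4)}
    sec = {f"s{i}": 1000.0 * rng.uniform(0.70, 0.80) for i in range(10)}
    hawks = {f"h{i}": 500.0 * (1 + 0.02 * i) for i in range(4)}
    doves = {f"d{i}": 500.0 * rng.uniform(0.45, 0.58) for i in range(10)}
    traits = {**prim, **sec, **hawks, **doves}

    mut = RoleAssignment.from_labels(
        "mutualism", {**{k: "primary_leader" for k in prim},
                      **{k: "secondary_leader" for k in sec}})
    agg = RoleAssignment.from_labels(
        "aggression", {**{k: "hawk" for k in hawks}, **{k: "dove" for k in doves}})

    up = tier_mass_ratio(mut, traits, ("secondary_leader", "primary_leader"),
                         threshold=PHI, alternative="greater")
    down = tier_mass_ratio(agg, traits, ("dove", "hawk"),
                           threshold=PHI, alternative="less")
    assert up.p < 0.001 and up.direction == "above"
    assert down.p < 0.001 and down.direction == "below"
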
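"""Pseudo-attractor search, cluster assignment, baseline update schemes."""

import numpy as np
import pandas as pd
import pytest

import boolbayes as bb
from boolbayes.attractors import (
    assign_attractors,
    baseline_update_rules,
    discretize_cluster_means,
    find_pseudo_attractors,
    random_restart_search,
)
from boolbayes.io import RegulatoryNetwork, SearchConfig

from .conftest import oracle_terminal_sccs


class TestFindPseudoAttractors:
    def test_toggle_switch_is_bistable(self, toggle):
        atts = find_pseudo_attractors(toggle.rules, (0, 0), SearchConfig(radius=2))
        assert {a.representative for a in atts} == {(0, 1), (1, 0)}
        assert all(a.is_fixed_point for a in atts)

    def test_constant_on_rules_fix_the_all_on_state(self):
        rules = {
            n: bb.Rule(target=n, regulators=(), V=np.ones(1), U=np.zeros(1))
            for n in ["X", "Y", "Z"]
        }
        atts = find_pseudo_attractors(rules, (1, 1, 1), SearchConfig(radius=3))
        assert [a.states for a in atts] == [frozenset({(1, 1, 1)})]

    def test_repressilator_has_one_cyclic_attractor(self, repressilator):
        atts = find_pseudo_attractors(
            repressilator.rules, (0, 0, 0), SearchConfig(radius=3)
        )
        assert len(atts) == 1
        assert atts[0].states == repressilator.attractors[0]
        assert not atts[0].is_fixed_point

    def test_coinflip_has_no_attractors_inside_a_bounded_ball(self, coinflip):
        atts = find_pseudo_attractors(coinflip.rules, (0,) * 5, SearchConfig(radius=4))
        assert atts == []

    def test_exactly_half_edges_are_retained(self):
        """Flip probability exactly at P_T survives pruning, so a state
        held only by 0.5 edges is not a singleton attractor."""
        rules = {
            "X": bb.Rule(target="X", regulators=("X",),
                         V=np.array([0.5, 0.5]), U=np.zeros(2)),
            "Y": bb.Rule(target="Y", regulators=(), V=np.array([0.0]),
                         U=np.zeros(1)),
        }
        atts = find_pseudo_attractors(rules, (0, 0), SearchConfig(radius=1))
        assert all((0, 0) not in a.states or len(a.states) > 1 for a in atts)

    def test_matches_exhaustive_oracle_on_random_networks(self, rng):
        """Bounded search with radius >= g equals the terminal SCCs of the
        independently built, pruned full STG (10 random probabilistic
        networks, g <= 6; the acceptance suite runs the larger sweep)."""
        for _ in range(10):
            g = int(rng.integers(3, 7))
            nodes = [f"N{i}" for i in range(g)]
            rules = {}
            for n in nodes:
                k = int(rng.integers(1, 4))
                regs = tuple(sorted(rng.choice(nodes, size=k, replace=False)))
                rules[n] = bb.Rule(target=n, regulators=regs,
                                   V=rng.uniform(0, 1, 2**k), U=np.zeros(2**k))
            found = find_pseudo_attractors(rules, (0,) * g, SearchConfig(radius=g))
            assert {a.states for a in found} == oracle_terminal_sccs(rules)


class TestRandomRestarts:
    def test_toggle_restarts_find_nothing_extra(self, toggle):
        cfg = SearchConfig(radius=2, n_random_starts=50, seed=0)
        sweep = random_restart_search(toggle.rules, cfg)
        assert {a.representative for a in sweep.attractors} == {(0, 1), (1, 0)}
        assert len(sweep.per_start) == 50

    def test_same_seed_same_attractors(self, hub):
        cfg = SearchConfig(radius=2, n_random_starts=20, seed=7)
        a = random_restart_search(hub.rules, cfg)
        b = random_restart_search(hub.rules, cfg)
        assert [x.states for x in a.attractors] == [x.states for x in b.attractors]
        assert a.per_start == b.per_start

    def test_radius_zero_only_finds_initial_fixed_points(self, toggle):
        cfg = SearchConfig(radius=0, n_random_starts=40, seed=1)
        sweep = random_restart_search(toggle.rules, cfg)
        for att in sweep.attractors:
            assert att.representative in {(0, 1), (1, 0)}


class TestClusterDiscretization:
    def test_threshold_with_tie_to_off(self):
        probs = pd.DataFrame(
            {"s0": [0.9, 0.1, 0.5], "s1": [0.9, 0.1, 0.5]},
            index=["A", "B", "C"],
        )
        binarized = bb.BinarizedMatrix(probabilities=probs, mixtures={})
        labels = bb.ClusterLabels({"s0": "x", "s1": "x"})
        net = RegulatoryNetwork.from_edges([], nodes=["A", "B", "C"])
        states = discretize_cluster_means(binarized, labels, net)
        assert states == {"x": (1, 0, 0)}

    def test_recovers_generating_states_at_high_separation(self, recovery_dataset,
                                                           recovery_binarized):
        _, network, _, states, _, labels = recovery_dataset
        refs = discretize_cluster_means(recovery_binarized, labels, network)
        assert refs == states


class TestAssignment:
    def test_exact_match_gets_distance_zero(self):
        att = bb.PseudoAttractor(states=frozenset({(1, 0)}))
        out = assign_attractors([att], {"hi": (1, 0), "lo": (0, 1)})
        assert out[0].cluster == "hi"
        assert out[0].distances == {"hi": 0, "lo": 2}
        assert not out[0].ambiguous

    def test_tie_goes_to_first_label_and_is_flagged(self):
        att = bb.PseudoAttractor(states=frozenset({(1, 1)}))
        out = assign_attractors([att], {"b": (1, 0), "a": (0, 1)})
        assert out[0].cluster == "a"
        assert out[0].ambiguous

    def test_intra_cluster_distances_smaller_than_inter(self, recovery_dataset,
                                                        recovery_binarized):
        _, network, true_rules, states, _, labels = recovery_dataset
        rules = bb.fit_all_rules(network, recovery_binarized)
        refs = discretize_cluster_means(recovery_binarized, labels, network)
        found = {}
        for state in refs.values():
            for a in find_pseudo_attractors(rules, state, SearchConfig(radius=6)):
                found[a.states] = a
        assigned = assign_attractors(found.values(), refs)
        for att in assigned:
            own = att.distances[att.cluster]
            others = [d for c, d in att.distances.items() if c != att.cluster]
            assert own < min(others)


class TestBaselineSchemes:
    @pytest.fixture()
    def signed_net(self):
        return RegulatoryNetwork.from_edges(
            [("ACT1", "T", "+"), ("ACT2", "T", "+"), ("INH", "T", "-")],
            nodes=["ACT1", "ACT2", "INH", "T"],
        )

    def test_inhibitory_dominant_truth_table(self, signed_net):
        rules = baseline_update_rules(signed_net, "inhibitory_dominant")
        rule = rules["T"]
        assert rule.regulators == ("ACT1", "ACT2", "INH")
        for leaf in range(8):
            a1, a2, inh = (leaf >> 2) & 1, (leaf >> 1) & 1, leaf & 1
            expected = 1.0 if (a1 or a2) and not inh else 0.0
            assert rule.V[leaf] == expected

    def test_majority_truth_table_is_strict(self, signed_net):
        rules = baseline_update_rules(signed_net, "majority")
        rule = rules["T"]
        for leaf in range(8):
            a1, a2, inh = (leaf >> 2) & 1, (leaf >> 1) & 1, leaf & 1
            assert rule.V[leaf] == (1.0 if a1 + a2 > inh else 0.0)
        # equal counts stay OFF: one activator ON, one inhibitor ON
        assert rule.V[0b101] == 0.0

    def test_unsigned_edge_rejected(self):
        net = RegulatoryNetwork.from_edges([("A", "B", "?")], nodes=["A", "B"])
        with pytest.raises(ValueError, match="sign"):
            baseline_update_rules(net, "majority")

    def test_baseline_rules_drive_the_dynamics(self, signed_net):
        rules = baseline_update_rules(signed_net, "inhibitory_dominant")
        atts = find_pseudo_attractors(rules, (0, 0, 0, 0), SearchConfig(radius=4))
        # with no regulators of their own, ACT1/ACT2/INH all decay to OFF
        assert {a.representative for a in atts} == {(0, 0, 0, 0)}
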
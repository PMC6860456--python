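"""Random-walk stability scores and master-TF classification."""

import numpy as np
import pytest

import boolbayes as bb
from boolbayes.dynamics import Dynamics
from boolbayes.io import WalkConfig
from boolbayes.perturb import (
    Perturbation,
    StabilityResult,
    classify_masters,
    cluster_scores,
    expected_escape_steps,
    random_walk,
    scan_perturbations,
    stability_score,
)

from .conftest import escape_chain_solve


def constant_rules(nodes, v):
    return {
        n: bb.Rule(target=n, regulators=(), V=np.array([float(v)]), U=np.zeros(1))
        for n in nodes
    }


class TestRandomWalk:
    def test_absorbing_state_censors_at_cap(self, rng):
        rules = constant_rules(["X", "Y", "Z"], 0.0)
        cfg = WalkConfig(escape_radius=1, n_walks=1, max_steps=50)
        assert random_walk(rules, (0, 0, 0), config=cfg, rng=rng) == 50

    def test_forced_flip_escapes_in_one_step(self, rng):
        rules = constant_rules(["X", "Y", "Z"], 1.0)
        cfg = WalkConfig(escape_radius=0, n_walks=1)
        assert random_walk(rules, (0, 0, 0), config=cfg, rng=rng) == 1

    def test_escape_radius_must_leave_room(self, coinflip):
        cfg = WalkConfig(escape_radius=5, n_walks=1)
        with pytest.raises(ValueError, match="escape is impossible"):
            random_walk(coinflip.rules, (0,) * 5, config=cfg)
        cfg = WalkConfig(escape_radius=4, n_walks=1)
        with pytest.raises(ValueError, match="escape is impossible"):
            random_walk(coinflip.rules, (0,) * 5,
                        Perturbation("C1", "knockdown"), cfg)

    def test_perturbation_modifies_the_start_state(self, hub, rng):
        # H held OFF: escape distance is measured to the modified start
        cfg = WalkConfig(escape_radius=2, n_walks=1, max_steps=500)
        steps = random_walk(hub.rules, (1, 1, 1, 1, 1),
                            Perturbation("H", "knockdown"), cfg, rng)
        assert steps >= 1


class TestWalkAgainstMarkovChain:
    def test_coinflip_mean_matches_birth_death_solve(self, coinflip):
        cfg = WalkConfig(escape_radius=4, n_walks=1000, seed=0)
        res = stability_score(coinflip.rules, (0,) * 5, Perturbation(), cfg)
        exact = escape_chain_solve(g=5, radius=4, p_flip=0.5)
        se = res.steps.std(ddof=1) / np.sqrt(res.n_walks)
        assert abs(res.mean_steps - exact) < 3 * se

    def test_exact_solver_agrees_with_independent_chain_solve(self, coinflip):
        exact = expected_escape_steps(coinflip.rules, (0,) * 5,
                                      Perturbation(), escape_radius=4)
        assert exact == pytest.approx(escape_chain_solve(5, 4, 0.5), rel=1e-9)
        held = expected_escape_steps(coinflip.rules, (0,) * 5,
                                     Perturbation("C1", "activation"),
                                     escape_radius=3)
        assert held == pytest.approx(escape_chain_solve(4, 3, 0.5), rel=1e-9)

    def test_hub_walks_match_exact_hitting_times(self, hub):
        cfg = WalkConfig(escape_radius=2, n_walks=1000, seed=0)
        for pert in [Perturbation(), Perturbation("H", "knockdown"),
                     Perturbation("H", "activation")]:
            res = stability_score(hub.rules, (1, 1, 1, 1, 1), pert, cfg)
            exact = expected_escape_steps(hub.rules, (1, 1, 1, 1, 1), pert,
                                          escape_radius=2)
            se = res.steps.std(ddof=1) / np.sqrt(res.n_walks)
            assert abs(res.mean_steps - exact) < 3 * se


class TestStabilityScore:
    def test_score_is_fractional_change(self):
        res = StabilityResult(
            start=(0,), perturbation=Perturbation("X", "knockdown"),
            steps=np.full(10, 80), reference_mean_steps=100.0,
            n_censored=0, seed=0,
        )
        assert res.score == pytest.approx(-0.2)
        assert res.histogram()["count"].sum() == res.n_walks

    def test_null_perturbation_scores_near_zero(self, coinflip):
        cfg = WalkConfig(escape_radius=4, n_walks=1000, seed=0)
        res = stability_score(coinflip.rules, (0,) * 5, Perturbation(), cfg)
        assert abs(res.score) < 0.05

    def test_hub_knockdown_destabilizes_its_on_attractor(self, hub):
        cfg = WalkConfig(escape_radius=2, n_walks=400, seed=0)
        res = stability_score(hub.rules, (1, 1, 1, 1, 1),
                              Perturbation("H", "knockdown"), cfg)
        assert res.score < 0
        exact_kd = expected_escape_steps(hub.rules, (1,) * 5,
                                         Perturbation("H", "knockdown"), 2)
        exact_ref = expected_escape_steps(hub.rules, (1,) * 5, Perturbation(), 2)
        assert exact_kd < exact_ref  # the Markov chain agrees

    def test_hub_activation_stabilizes(self, hub):
        cfg = WalkConfig(escape_radius=2, n_walks=400, seed=0)
        res = stability_score(hub.rules, (1, 1, 1, 1, 1),
                              Perturbation("H", "activation"), cfg)
        assert res.score > 0

    def test_holding_an_attractor_value_removes_no_other_escape_channels(self, hub):
        """Fixing a TF at its attractor value only deletes that TF's own
        flip channel; every other TF's flip probability is unchanged."""
        dyn = Dynamics(hub.rules)
        state = (1, 1, 1, 1, 1)
        before = {n: dyn.flip_probability(state, n) for n in dyn.nodes}
        channels_before = {n for n, p in before.items() if p >= 0.5}
        channels_after = {
            n for n in dyn.nodes if n != "H" and dyn.flip_probability(state, n) >= 0.5
        }
        assert channels_after <= channels_before


class TestScanAndClassify:
    def test_scan_cardinality_on_toggle(self, toggle):
        atts = bb.find_pseudo_attractors(toggle.rules, (0, 0),
                                         bb.SearchConfig(radius=2))
        cfg = WalkConfig(escape_radius=0, n_walks=40, max_steps=200, seed=0)
        results = scan_perturbations(toggle.rules, atts, cfg)
        # per attractor: 1 reference + 2 TFs x 2 modes
        assert len(results) == 2 * (1 + 4)
        refs = [r for r in results if r.perturbation.mode == "none"]
        assert all(r.score == 0.0 for r in refs)

    def test_toggle_knockdown_of_active_tf_is_destabilizing(self, toggle):
        att = bb.PseudoAttractor(states=frozenset({(1, 0)}))  # A ON, B OFF
        cfg = WalkConfig(escape_radius=0, n_walks=40, max_steps=200, seed=0)
        res = stability_score(toggle.rules, att, Perturbation("A", "knockdown"),
                              cfg)
        assert res.score < 0

    def test_toggle_activation_of_active_tf_never_hurts(self, toggle):
        att = bb.PseudoAttractor(states=frozenset({(1, 0)}))
        cfg = WalkConfig(escape_radius=0, n_walks=40, max_steps=200, seed=0)
        res = stability_score(toggle.rules, att, Perturbation("A", "activation"),
                              cfg)
        assert res.score >= 0

    def test_scan_is_reproducible_and_order_independent(self, hub):
        att1 = bb.PseudoAttractor(states=frozenset({(1, 1, 1, 1, 1)}), cluster="on")
        att2 = bb.PseudoAttractor(states=frozenset({(0, 0, 0, 0, 0)}), cluster="off")
        cfg = WalkConfig(escape_radius=2, n_walks=30, max_steps=500, seed=5)
        a = scan_perturbations(hub.rules, [att1, att2], cfg)
        b = scan_perturbations(hub.rules, [att2, att1], cfg)
        key = lambda r: (r.start, r.perturbation.label())
        scores_a = {key(r): r.mean_steps for r in a}
        scores_b = {key(r): r.mean_steps for r in b}
        assert scores_a == scores_b

    def test_cluster_scores_average_over_attractors(self, hub):
        mk = lambda start, cluster, mean, ref: StabilityResult(
            start=start, perturbation=Perturbation("H", "knockdown"),
            steps=np.full(4, mean), reference_mean_steps=ref,
            n_censored=0, seed=0, cluster=cluster,
        )
        df = cluster_scores([mk((1,), "c", 50, 100), mk((0,), "c", 90, 100)])
        assert len(df) == 1
        assert df["score"].iloc[0] == pytest.approx((-0.5 + -0.1) / 2)

    @pytest.mark.parametrize(
        "mode,score,expect",
        [
            ("knockdown", -0.25, "master_regulators"),
            ("knockdown", -0.1, None),
            ("activation", -0.3, "master_destabilizers"),
            ("activation", -0.15, None),
        ],
    )
    def test_master_classification_cutoff(self, mode, score, expect):
        import pandas as pd

        df = pd.DataFrame([{"cluster": "c", "tf": "X", "mode": mode,
                            "score": score}])
        out = classify_masters(df)
        sets = out["c"]
        if expect is None:
            assert not sets["master_regulators"] and not sets["master_destabilizers"]
        else:
            assert sets[expect] == {"X"}
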
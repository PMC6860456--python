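"""Score in-silico TF perturbations as stabilizers or destabilizers.

Uses the self-activating hub fixture: a TF H that sustains itself and four
downstream targets.  At the all-ON attractor, random walks measure how many
update events pass before the state drifts more than 2 TF changes away.
Holding H OFF (knockdown) collapses the attractor's support, so walks
escape sooner and the stability score goes strongly negative; holding H ON
removes its only flip channel and stabilizes.
"""

import boolbayes as bb

fixture = bb.fixtures()["self_activator_hub"]
attractor = bb.PseudoAttractor(states=frozenset({(1, 1, 1, 1, 1)}), cluster="ON")

config = bb.WalkConfig(escape_radius=2, n_walks=1000, seed=0)
results = bb.scan_perturbations(fixture.rules, [attractor], config)

print(f"{'TF':<4} {'mode':<12} {'mean steps':>10} {'score':>8}")
for res in results:
    tf = res.perturbation.tf or "-"
    print(f"{tf:<4} {res.perturbation.mode:<12} {res.mean_steps:>10.1f} "
          f"{res.score:>8.3f}")

scores = bb.cluster_scores(results)
masters = bb.classify_masters(scores, threshold=-0.2)
print()
print("master regulators of ON (knockdown score <= -0.2):",
      sorted(masters["ON"]["master_regulators"]))
print("master destabilizers of ON (activation score <= -0.2):",
      sorted(masters["ON"]["master_destabilizers"]))
print()
print("score = (mean escape steps - unperturbed mean) / unperturbed mean;")
print("negative scores mean the perturbation pushes the cell out of the")
print("phenotype's neighborhood sooner.")
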
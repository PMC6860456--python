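"""Pseudo-attractor search, subtype assignment, and baseline update schemes.

A pseudo-attractor is a set of states the dynamics is unlikely to leave:
after pruning every STG edge whose flip probability is strictly below the
threshold P_T, a pseudo-attractor is a strongly connected component that
does not contain the out-of-bounds sink and has no retained edge leaving
it.  A singleton pseudo-attractor is exactly a state at which every TF's
flip probability is below P_T (at the default P_T = 0.5, every TF has at
least a 50% chance of keeping its value per update).

Initial states for the search come from discretized per-cluster mean
ON-probabilities; a sweep over random initial states guards against
attractors far from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .binarize import BinarizedMatrix
from .dynamics import (
    OOB,
    Dynamics,
    State,
    build_bounded_stg,
    hamming,
)
from .io import ClusterLabels, RegulatoryNetwork, SearchConfig
from .rules import Rule

__all__ = [
    "PseudoAttractor",
    "find_pseudo_attractors",
    "RestartSearch",
    "random_restart_search",
    "discretize_cluster_means",
    "assign_attractors",
    "baseline_update_rules",
]


@dataclass(frozen=True)
class PseudoAttractor:
    """A terminal SCC of the pruned STG.

    ``representative`` (the lexicographically smallest member bitstring)
    seeds downstream random walks; ``cluster``/``ambiguous``/``distances``
    are filled by :func:`assign_attractors`.
    """

    states: frozenset[State]
    cluster: str | None = None
    ambiguous: bool = False
    distances: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("pseudo-attractor must have at least one state")

    @property
    def representative(self) -> State:
        return min(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def __len__(self) -> int:
        return len(self.states)


def find_pseudo_attractors(
    rules: Dynamics | Mapping[str, Rule],
    init_state: Sequence[int],
    config: SearchConfig = SearchConfig(),
) -> list[PseudoAttractor]:
    """Bounded pseudo-attractor search around one initial state.

    Builds the STG out to ``config.radius`` TF changes, prunes edges with
    flip probability strictly below ``config.threshold``, and returns the
    strongly connected components with no sink membership and no retained
    out-edges, sorted by representative state.
    """
    dyn = Dynamics.ensure(rules)
    radius = min(config.radius, dyn.g)  # distances never exceed g
    stg = build_bounded_stg(dyn, init_state, radius, config.max_vertices)
    pruned = stg.pruned(config.threshold)
    found = []
    for scc in nx.strongly_connected_components(pruned):
        if OOB in scc:
            continue
        if any(v not in scc for u in scc for v in pruned.successors(u)):
            continue
        found.append(PseudoAttractor(states=frozenset(scc)))
    return sorted(found, key=lambda a: a.representative)


@dataclass(frozen=True)
class RestartSearch:
    """Random-restart sweep result: deduplicated attractors plus a per-start
    log of (initial state, states explored, attractors found)."""

    attractors: tuple[PseudoAttractor, ...]
    per_start: tuple[dict, ...]


def random_restart_search(
    rules: Dynamics | Mapping[str, Rule],
    config: SearchConfig = SearchConfig(),
) -> RestartSearch:
    """Search the neighborhoods of ``config.n_random_starts`` uniform random
    initial states and union the deduplicated pseudo-attractors."""
    dyn = Dynamics.ensure(rules)
    rng = np.random.default_rng(config.seed)
    seen: dict[frozenset[State], PseudoAttractor] = {}
    log = []
    for _ in range(config.n_random_starts):
        start = tuple(int(b) for b in rng.integers(0, 2, dyn.g))
        found = find_pseudo_attractors(dyn, start, config)
        for att in found:
            seen.setdefault(att.states, att)
        log.append(
            {
                "start": "".join(map(str, start)),
                "n_attractors": len(found),
            }
        )
    attractors = tuple(sorted(seen.values(), key=lambda a: a.representative))
    return RestartSearch(attractors=attractors, per_start=tuple(log))


def discretize_cluster_means(
    binarized: BinarizedMatrix,
    labels: ClusterLabels,
    network: RegulatoryNetwork,
) -> dict[str, State]:
    """Per-cluster initial states: mean ON-probability per TF across the
    cluster's samples, thresholded at 0.5 (ties go to OFF)."""
    probs = binarized.probabilities
    missing = [n for n in network.nodes if n not in probs.index]
    if missing:
        raise ValueError(f"network nodes absent from binarized matrix: {missing}")
    states: dict[str, State] = {}
    for cluster in labels.clusters:
        samples = labels.samples_in(cluster)
        if not samples:
            raise ValueError(f"cluster '{cluster}' has no samples")
        means = probs.loc[list(network.nodes), samples].mean(axis=1)
        states[cluster] = tuple(int(m > 0.5) for m in means)
    return states


def assign_attractors(
    attractors: Iterable[PseudoAttractor],
    references: Mapping[str, State],
) -> list[PseudoAttractor]:
    """Assign each attractor to the cluster whose reference state is nearest
    in Hamming distance (measured at the representative state).

    Ties go to the alphabetically first cluster and are flagged ambiguous;
    all pairwise distances are retained for reporting.
    """
    assigned = []
    for att in attractors:
        rep = att.representative
        distances = {c: hamming(rep, ref) for c, ref in references.items()}
        best = min(distances.values())
        winners = sorted(c for c, d in distances.items() if d == best)
        assigned.append(
            replace(
                att,
                cluster=winners[0],
                ambiguous=len(winners) > 1,
                distances=distances,
            )
        )
    return assigned


def baseline_update_rules(
    network: RegulatoryNetwork, scheme: str
) -> dict[str, Rule]:
    """Deterministic comparison rules built from edge signs alone.

    ``inhibitory_dominant``: the target turns ON only when at least one
    activator is ON and all inhibitors are OFF.  ``majority``: the target
    turns ON when strictly more activators than inhibitors are ON.  Both
    schemes require every incoming edge to carry a definite sign.
    """
    if scheme not in ("inhibitory_dominant", "majority"):
        raise ValueError(f"unknown update scheme '{scheme}'")
    rules: dict[str, Rule] = {}
    for target in network.nodes:
        signed = network.signed_regulators_of(target)
        unsigned = [src for src, sign in signed if sign == "?"]
        if unsigned:
            raise ValueError(
                f"edges {unsigned}->{target} carry no sign; the "
                f"{scheme} scheme needs signed edges"
            )
        regulators = tuple(src for src, _ in signed)
        n = len(regulators)
        V = np.zeros(2**n)
        for leaf in range(2**n):
            bits = [(leaf >> (n - 1 - k)) & 1 for k in range(n)]
            act_on = sum(b for b, (_, s) in zip(bits, signed) if s == "+")
            inh_on = sum(b for b, (_, s) in zip(bits, signed) if s == "-")
            if scheme == "inhibitory_dominant":
                V[leaf] = 1.0 if act_on >= 1 and inh_on == 0 else 0.0
            else:
                V[leaf] = 1.0 if act_on > inh_on else 0.0
        rules[target] = Rule(
            target=target, regulators=regulators, V=V, U=np.zeros(2**n)
        )
    return rules
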
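"""Ground-truth generators and canonical fixtures.

The generator emulates the study design the inference is meant for: a small
TF network whose stable states (fixed-point attractors) are observed as
groups of steady-state expression samples.  Each cluster of samples sits at
one attractor; a gene's expression is drawn from Normal(mu_on, sigma^2) if
the attractor has it ON and Normal(mu_off, sigma^2) if OFF, truncated at
zero to match the non-negative log-expression input contract.  Defaults
(mu_off=1, mu_on=6, sigma=0.5) give a 10-sigma gap between the component
means, so binarization is near-deterministic; a stress setting around
sigma=1.5 exercises the uncertain regime.

Random networks are resampled until they have exactly ``n_clusters``
fixed-point attractors under exhaustive asynchronous analysis and until
every gene differs between at least two of those attractors.  The second
condition mirrors how such networks are assembled in practice — from TFs
that are differentially expressed between the phenotypes — and matters
because a gene constant across all clusters is unimodal in expression and
carries no signal for a two-component binarizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import State
from .io import ClusterLabels, ExpressionMatrix, RegulatoryNetwork
from .rules import Rule

__all__ = [
    "SyntheticSpec",
    "random_boolean_network",
    "enumerate_fixed_points",
    "expression_from_states",
    "Fixture",
    "fixtures",
]

EXHAUSTIVE_BOUND = 12


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator."""

    n_nodes: int = 12
    max_in_degree: int = 3
    n_clusters: int = 4
    samples_per_cluster: int = 12
    mu_off: float = 1.0
    mu_on: float = 6.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def _node_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def enumerate_fixed_points(rules: Mapping[str, Rule]) -> list[State]:
    """All fixed points of deterministic rules by exhaustive enumeration.

    A fixed point is a state where every node's rule output equals its
    current value, hence no update can change anything.
    """
    nodes = sorted(rules)
    n = len(nodes)
    if n > EXHAUSTIVE_BOUND:
        raise ValueError(
            f"exhaustive fixed-point check limited to {EXHAUSTIVE_BOUND} nodes"
        )
    index = {node: i for i, node in enumerate(nodes)}
    codes = np.arange(2**n)
    states = ((codes[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(int)
    ok = np.ones(2**n, dtype=bool)
    for node in nodes:
        rule = rules[node]
        reg_idx = [index[r] for r in rule.regulators]
        if reg_idx:
            bits = states[:, reg_idx]
            leaf = np.zeros(2**n, dtype=int)
            for col in bits.T:
                leaf = (leaf << 1) | col
            out = np.asarray(rule.V)[leaf]
        else:
            out = np.full(2**n, rule.V[0])
        ok &= out == states[:, index[node]]
    return [tuple(int(b) for b in states[k]) for k in np.nonzero(ok)[0]]


def random_boolean_network(
    spec: SyntheticSpec,
    max_tries: int = 50_000,
    require_marker_genes: bool | None = None,
) -> tuple[RegulatoryNetwork, dict[str, Rule]]:
    """Random network + deterministic truth tables with a prescribed
    attractor inventory.

    Resamples until the network has exactly ``spec.n_clusters`` fixed
    points (at least one if ``n_clusters`` is 1) and — when
    ``require_marker_genes`` (default: n_clusters > 1) — until every gene
    differs between at least two of those fixed points.  Same seed, same
    network.
    """
    if spec.n_nodes > EXHAUSTIVE_BOUND:
        raise ValueError(
            f"n_nodes={spec.n_nodes} exceeds the exhaustive-check bound "
            f"({EXHAUSTIVE_BOUND}); supply rules explicitly for larger networks"
        )
    if require_marker_genes is None:
        require_marker_genes = spec.n_clusters > 1
    nodes = _node_names(spec.n_nodes)
    n = spec.n_nodes
    rng = np.random.default_rng(spec.seed)
    codes = np.arange(2**n)
    all_states = ((codes[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(int)
    for _ in range(max_tries):
        draw: list[tuple[np.ndarray, np.ndarray]] = []
        ok = np.ones(2**n, dtype=bool)
        for i in range(n):
            k = int(rng.integers(1, spec.max_in_degree + 1))
            regs = np.sort(rng.permutation(n)[:k])
            V = rng.integers(0, 2, size=2**k)
            draw.append((regs, V))
            leaf = np.zeros(2**n, dtype=int)
            for col in all_states[:, regs].T:
                leaf = (leaf << 1) | col
            ok &= V[leaf] == all_states[:, i]
        n_fps = int(ok.sum())
        if spec.n_clusters == 1:
            if n_fps == 0:
                continue
        elif n_fps != spec.n_clusters:
            continue
        fps_arr = all_states[ok]
        if require_marker_genes and n_fps > 1:
            if (fps_arr.min(axis=0) == fps_arr.max(axis=0)).any():
                continue
        edges = []
        rules = {}
        for i, node in enumerate(nodes):
            regs_idx, V = draw[i]
            regs = tuple(nodes[r] for r in regs_idx)
            rules[node] = Rule(target=node, regulators=regs,
                               V=V.astype(float), U=np.zeros(len(V)))
            edges.extend((r, node, "?") for r in regs)
        network = RegulatoryNetwork.from_edges(edges, nodes=nodes)
        return network, rules
    raise RuntimeError(
        f"no network with {spec.n_clusters} fixed points found in "
        f"{max_tries} tries; relax the generator parameters"
    )


def expression_from_states(
    states: Mapping[str, State],
    network: RegulatoryNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ClusterLabels]:
    """Sample bimodal expression data around attractor states.

    ``states`` maps cluster label -> attractor state over ``network.nodes``.
    Each cluster contributes ``spec.samples_per_cluster`` samples; a gene's
    value is Normal(mu_on, sigma^2) where the state bit is 1 and
    Normal(mu_off, sigma^2) where it is 0, redrawn while negative.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    nodes = list(network.nodes)
    columns: dict[str, np.ndarray] = {}
    mapping: dict[str, str] = {}
    for cluster in sorted(states):
        state = states[cluster]
        if len(state) != len(nodes):
            raise ValueError(
                f"state for cluster '{cluster}' has length {len(state)}, "
                f"expected {len(nodes)}"
            )
        means = np.where(np.asarray(state) == 1, spec.mu_on, spec.mu_off)
        for k in range(spec.samples_per_cluster):
            vals = rng.normal(means, spec.sigma)
            while (vals < 0).any():  # truncate at 0 by redraw
                neg = vals < 0
                vals[neg] = rng.normal(means[neg], spec.sigma)
            sample = f"{cluster}_s{k}"
            columns[sample] = vals
            mapping[sample] = cluster
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=nodes))
    return matrix, ClusterLabels(mapping)


@dataclass(frozen=True)
class Fixture:
    """A canonical small network with a known attractor inventory."""

    name: str
    network: RegulatoryNetwork
    rules: dict[str, Rule]
    attractors: tuple[frozenset[State], ...]
    description: str


def _rule(target: str, regulators: Sequence[str], V: Sequence[float]) -> Rule:
    V = np.asarray(V, dtype=float)
    return Rule(target=target, regulators=tuple(regulators), V=V,
                U=np.zeros(len(V)))


def fixtures() -> dict[str, Fixture]:
    """Canonical fixtures with hand-checkable dynamics.

    * ``toggle_switch`` — two mutually inhibiting TFs; fixed points (1,0)
      and (0,1) (node order A, B).
    * ``repressilator`` — three-TF inhibition cycle; no fixed points, one
      six-state cyclic attractor.
    * ``self_activator_hub`` — a self-sustaining hub H driving four targets
      D1..D4; the all-ON and all-OFF states are pseudo-attractors and hub
      knockdown strictly shortens escape times from the ON attractor.
    * ``independent_coinflip`` — five unregulated TFs with constant rule
      output 0.5: every flip probability is exactly 0.5, all STG edges are
      retained at the default threshold, and any bounded search with
      radius < g finds no pseudo-attractor.
    """
    out: dict[str, Fixture] = {}

    net = RegulatoryNetwork.from_edges([("B", "A", "-"), ("A", "B", "-")])
    out["toggle_switch"] = Fixture(
        name="toggle_switch",
        network=net,
        rules={"A": _rule("A", ["B"], [1, 0]), "B": _rule("B", ["A"], [1, 0])},
        attractors=(frozenset({(0, 1)}), frozenset({(1, 0)})),
        description="mutual inhibition; bistable",
    )

    net = RegulatoryNetwork.from_edges(
        [("A", "B", "-"), ("B", "C", "-"), ("C", "A", "-")]
    )
    cycle = frozenset(
        {(1, 0, 0), (1, 0, 1), (0, 0, 1), (0, 1, 1), (0, 1, 0), (1, 1, 0)}
    )
    out["repressilator"] = Fixture(
        name="repressilator",
        network=net,
        rules={
            "A": _rule("A", ["C"], [1, 0]),
            "B": _rule("B", ["A"], [1, 0]),
            "C": _rule("C", ["B"], [1, 0]),
        },
        attractors=(cycle,),
        description="3-node inhibition cycle; single cyclic attractor",
    )

    hub_nodes = ["D1", "D2", "D3", "D4", "H"]
    edges = [("H", "H", "+")] + [("H", d, "+") for d in hub_nodes[:4]]
    rules = {"H": _rule("H", ["H"], [0.05, 0.95])}
    for d in hub_nodes[:4]:
        rules[d] = _rule(d, ["H"], [0.25, 0.8])
    out["self_activator_hub"] = Fixture(
        name="self_activator_hub",
        network=RegulatoryNetwork.from_edges(edges, nodes=hub_nodes),
        rules=rules,
        attractors=(frozenset({(0, 0, 0, 0, 0)}), frozenset({(1, 1, 1, 1, 1)})),
        description="self-sustaining hub required for ON-attractor stability",
    )

    coin_nodes = [f"C{i}" for i in range(1, 6)]
    out["independent_coinflip"] = Fixture(
        name="independent_coinflip",
        network=RegulatoryNetwork.from_edges([], nodes=coin_nodes),
        rules={c: _rule(c, [], [0.5]) for c in coin_nodes},
        attractors=(),
        description="five unregulated TFs, all flip probabilities exactly 0.5",
    )
    return out
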
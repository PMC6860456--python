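"""General-asynchronous stochastic dynamics over probabilistic rules.

A network state is an ordered binary tuple over the g nodes (node order is
lexicographic).  At every update event one non-fixed TF is chosen uniformly
at random; its rule supplies the ON-probability at the current regulator
configuration, and a weighted coin decides the TF's next value.  The flip
probability of a TF is therefore the ON-probability if the TF is currently
OFF and one minus it if the TF is ON, so a TF whose rule confidently agrees
with its current value almost never flips.

The bounded state-transition graph (STG) explores the Hamming ball of a
given radius around an initial state: every in-bounds state gets g weighted
out-edges (one per TF, weight = that TF's flip probability); states beyond
the radius get a single weight-1 edge to an out-of-bounds sink, which
prevents anything that escapes the ball from being mistaken for an
attractor.  Self-transitions (the coin not flipping) are implicit and not
stored as edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .rules import Rule

__all__ = [
    "OOB",
    "State",
    "hamming",
    "state_to_str",
    "str_to_state",
    "Dynamics",
    "rule_output_at_state",
    "flip_probability",
    "step",
    "TransitionGraph",
    "build_bounded_stg",
]

State = tuple[int, ...]

#: the out-of-bounds sink vertex of bounded transition graphs
OOB = "__out_of_bounds__"


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    """Hamming distance: number of TFs whose ON/OFF values differ."""
    if len(a) != len(b):
        raise ValueError("states must have equal length")
    return sum(x != y for x, y in zip(a, b))


def state_to_str(state: Sequence[int]) -> str:
    return "".join(str(int(b)) for b in state)


def str_to_state(s: str) -> State:
    return tuple(int(c) for c in s)


class Dynamics:
    """Compiled rule set: node order, per-node regulator indices and rule
    tables, with the update primitives used by searches and random walks."""

    def __init__(self, rules: Mapping[str, Rule]):
        self.rules = dict(rules)
        self.nodes: tuple[str, ...] = tuple(sorted(rules))
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._reg_idx: list[np.ndarray] = []
        self._tables: list[np.ndarray] = []
        for node in self.nodes:
            rule = rules[node]
            missing = [r for r in rule.regulators if r not in self.index]
            if missing:
                raise ValueError(
                    f"rule for {node} references unknown regulators {missing}"
                )
            self._reg_idx.append(np.array([self.index[r] for r in rule.regulators],
                                          dtype=int))
            self._tables.append(np.asarray(rule.V, dtype=float))

    @classmethod
    def ensure(cls, rules: "Dynamics | Mapping[str, Rule]") -> "Dynamics":
        return rules if isinstance(rules, Dynamics) else cls(rules)

    @property
    def g(self) -> int:
        return len(self.nodes)

    def _leaf_index(self, state: Sequence[int], i: int) -> int:
        idx = self._reg_idx[i]
        j = 0
        for k in idx:
            j = (j << 1) | int(state[k])
        return j

    def p_on(self, state: Sequence[int], node: str) -> float:
        """Rule output (ON-probability) of ``node`` at ``state``: the leaf
        value selected by the regulators' current binary values."""
        if node not in self.index:
            raise KeyError(f"unknown TF '{node}'")
        i = self.index[node]
        return float(self._tables[i][self._leaf_index(state, i)])

    def flip_probability(self, state: Sequence[int], node: str) -> float:
        """Probability the weighted coin changes ``node``'s value: the
        ON-probability if the node is OFF, its complement if ON."""
        if node not in self.index:
            raise KeyError(f"unknown TF '{node}'")
        i = self.index[node]
        p_on = self._tables[i][self._leaf_index(state, i)]
        return float(p_on if state[i] == 0 else 1.0 - p_on)

    def flip_vector(self, state: Sequence[int]) -> np.ndarray:
        """Flip probabilities of all g TFs at ``state``."""
        out = np.empty(self.g)
        for i in range(self.g):
            p_on = self._tables[i][self._leaf_index(state, i)]
            out[i] = p_on if state[i] == 0 else 1.0 - p_on
        return out

    def step(
        self,
        state: State,
        fixed_tfs: Iterable[str] = (),
        rng: np.random.Generator | None = None,
    ) -> State:
        """One general-asynchronous update event.

        Chooses one non-fixed TF uniformly, flips it with its flip
        probability, and returns the (possibly identical) successor.
        Consumes exactly two random draws (index, uniform).
        """
        rng = np.random.default_rng() if rng is None else rng
        fixed = {self.index[t] for t in fixed_tfs}
        free = [i for i in range(self.g) if i not in fixed]
        if not free:
            raise ValueError("all TFs are fixed; nothing to update")
        i = free[int(rng.integers(len(free)))]
        r = rng.random()
        p_on = self._tables[i][self._leaf_index(state, i)]
        p_flip = p_on if state[i] == 0 else 1.0 - p_on
        if r < p_flip:
            flipped = list(state)
            flipped[i] = 1 - flipped[i]
            return tuple(flipped)
        return tuple(state)


def rule_output_at_state(
    rules: Dynamics | Mapping[str, Rule], state: Sequence[int], tf: str
) -> float:
    """Functional wrapper for :meth:`Dynamics.p_on`."""
    return Dynamics.ensure(rules).p_on(state, tf)


def flip_probability(
    rules: Dynamics | Mapping[str, Rule], state: Sequence[int], tf: str
) -> float:
    """Functional wrapper for :meth:`Dynamics.flip_probability`."""
    return Dynamics.ensure(rules).flip_probability(state, tf)


def step(
    rules: Dynamics | Mapping[str, Rule],
    state: State,
    fixed_tfs: Iterable[str] = (),
    rng: np.random.Generator | None = None,
) -> State:
    """Functional wrapper for :meth:`Dynamics.step`."""
    return Dynamics.ensure(rules).step(state, fixed_tfs, rng)


@dataclass(frozen=True)
class TransitionGraph:
    """Bounded STG: state tuples plus the :data:`OOB` sink, directed edges
    labeled with flip probabilities."""

    graph: nx.DiGraph
    init_state: State
    radius: int

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes() - 1  # exclude the sink

    def pruned(self, threshold: float) -> nx.DiGraph:
        """Copy with every edge of weight strictly below ``threshold``
        removed (weight exactly at the threshold is retained)."""
        pruned = self.graph.copy()
        drop = [
            (u, v)
            for u, v, w in pruned.edges(data="weight")
            if w < threshold
        ]
        pruned.remove_edges_from(drop)
        return pruned

    def edge_table(self):
        """Edge list as (state bitstring, tf or sink marker, weight) rows."""
        import pandas as pd

        rows = []
        for u, v, data in self.graph.edges(data=True):
            rows.append(
                {
                    "state": state_to_str(u),
                    "tf": data.get("tf", ""),
                    "successor": OOB if v == OOB else state_to_str(v),
                    "flip_probability": data["weight"],
                }
            )
        return pd.DataFrame(rows)


def build_bounded_stg(
    rules: Dynamics | Mapping[str, Rule],
    init_state: Sequence[int],
    radius: int,
    max_vertices: int = 2_000_000,
) -> TransitionGraph:
    """Breadth-first construction of the bounded STG around ``init_state``.

    States within ``radius`` of the start get one out-edge per TF weighted
    by that TF's flip probability; states beyond the radius get a single
    weight-1 edge to the sink.  Raises ``MemoryError`` if the vertex count
    would exceed ``max_vertices``.
    """
    dyn = Dynamics.ensure(rules)
    init = tuple(int(b) for b in init_state)
    if len(init) != dyn.g:
        raise ValueError(f"initial state has length {len(init)}, expected {dyn.g}")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    graph = nx.DiGraph()
    graph.add_node(OOB)
    graph.add_node(init)
    pending = [init]
    while pending:
        state = pending.pop()
        if hamming(state, init) > radius:
            graph.add_edge(state, OOB, weight=1.0)
            continue
        flips = dyn.flip_vector(state)
        for i, node in enumerate(dyn.nodes):
            neighbor = list(state)
            neighbor[i] = 1 - neighbor[i]
            neighbor = tuple(neighbor)
            if neighbor not in graph:
                if graph.number_of_nodes() >= max_vertices:
                    raise MemoryError(
                        f"bounded STG exceeded {max_vertices} vertices; "
                        f"reduce the search radius"
                    )
                graph.add_node(neighbor)
                pending.append(neighbor)
            graph.add_edge(state, neighbor, weight=float(flips[i]), tf=node)
    return TransitionGraph(graph=graph, init_state=init, radius=radius)
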
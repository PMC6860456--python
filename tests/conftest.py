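"""Shared fixtures: canonical networks and a seeded recovery dataset."""

from __future__ import annotations

import numpy as np
import pytest

import boolbayes as bb
from boolbayes.dynamics import Dynamics

SUITE_SEED = 0


@pytest.fixture(scope="session")
def canonical():
    return bb.fixtures()


@pytest.fixture(scope="session")
def toggle(canonical):
    return canonical["toggle_switch"]


@pytest.fixture(scope="session")
def repressilator(canonical):
    return canonical["repressilator"]


@pytest.fixture(scope="session")
def hub(canonical):
    return canonical["self_activator_hub"]


@pytest.fixture(scope="session")
def coinflip(canonical):
    return canonical["independent_coinflip"]


def make_recovery_dataset(seed: int, sigma: float = 0.5):
    """One ground-truth study: a 12-node network with four fixed-point
    attractors realized as sample clusters of bimodal expression."""
    spec = bb.SyntheticSpec(
        n_nodes=12, n_clusters=4, samples_per_cluster=12, sigma=sigma, seed=seed
    )
    network, true_rules = bb.random_boolean_network(spec)
    fps = bb.enumerate_fixed_points(true_rules)
    states = {f"c{k}": fp for k, fp in enumerate(fps)}
    matrix, labels = bb.expression_from_states(states, network, spec)
    return spec, network, true_rules, states, matrix, labels


@pytest.fixture(scope="session")
def recovery_dataset():
    return make_recovery_dataset(seed=3)


@pytest.fixture(scope="session")
def recovery_binarized(recovery_dataset):
    _, _, _, _, matrix, _ = recovery_dataset
    return bb.fit_binarizer(matrix, seed=SUITE_SEED)


def naive_fit_oracle(R_prime, T_prime, min_leaf_evidence=0.01):
    """Independent brute-force rule fit: plain loops over leaves and
    observations applying the published formulas, plus the published
    evidence floor.  Deliberately unvectorized."""
    R = np.asarray(R_prime, dtype=float)
    T = np.asarray(T_prime, dtype=float)
    m, n = R.shape
    n_leaves = 2**n
    W = np.zeros((m, n_leaves))
    for i in range(m):
        for j in range(n_leaves):
            w = 1.0
            for k in range(n):
                bit = (j >> (n - 1 - k)) & 1
                w *= R[i, k] if bit else 1.0 - R[i, k]
            W[i, j] = w
    V = np.zeros(n_leaves)
    U = np.zeros(n_leaves)
    for j in range(n_leaves):
        wmax = 0.0
        wsum = 0.0
        num = 0.0
        for i in range(m):
            wmax = max(wmax, W[i, j])
            wsum += W[i, j]
            num += T[i] * W[i, j]
        U[j] = 1.0 - wmax
        denom = wsum + U[j]
        V[j] = (num + 0.5 * U[j]) / denom if denom > 0 else 0.5
        if wsum < min_leaf_evidence:
            V[j] = 0.5
        V[j] = min(1.0, max(0.0, V[j]))
    return V, U, W


def oracle_terminal_sccs(rules, threshold=0.5):
    """Independent exhaustive attractor oracle: build the full pruned STG
    over all 2^g states with plain loops, find strongly connected
    components via scipy.sparse.csgraph, and keep the terminal ones."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    nodes = sorted(rules)
    g = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    n_states = 2**g
    rows, cols = [], []
    for code in range(n_states):
        state = [(code >> (g - 1 - i)) & 1 for i in range(g)]
        for i, node in enumerate(nodes):
            rule = rules[node]
            leaf = 0
            for reg in rule.regulators:
                leaf = (leaf << 1) | state[index[reg]]
            p_on = float(rule.V[leaf])
            p_flip = p_on if state[i] == 0 else 1.0 - p_on
            if p_flip >= threshold:  # edge survives pruning (strict <)
                rows.append(code)
                cols.append(code ^ (1 << (g - 1 - i)))
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_states, n_states)
    )
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    terminal = set(range(n_comp))
    for r, c in zip(rows, cols):
        if labels[r] != labels[c]:
            terminal.discard(labels[r])
    out = []
    for comp in terminal:
        members = np.nonzero(labels == comp)[0]
        out.append(
            frozenset(
                tuple((int(code) >> (g - 1 - i)) & 1 for i in range(g))
                for code in members
            )
        )
    return set(out)


def escape_chain_solve(g: int, radius: int, p_flip: float = 0.5) -> float:
    """Expected escape steps for g independent TFs with a constant flip
    probability: exact solve of the birth-death chain on Hamming distance
    (distance d goes up with p_flip*(g-d)/g, down with p_flip*d/g)."""
    n = radius + 1
    Q = np.zeros((n, n))
    for d in range(n):
        up = p_flip * (g - d) / g
        down = p_flip * d / g
        if d + 1 < n:
            Q[d, d + 1] = up
        Q[d, d] = 1.0 - up - down
        if d - 1 >= 0:
            Q[d, d - 1] = down
    E = np.linalg.solve(np.eye(n) - Q, np.ones(n))
    return float(E[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
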
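"""Probabilistic Boolean rule fitting from binarized steady-state data.

A target TF with N regulators has a rule vector V of length 2^N: one entry
per regulator configuration (leaf), holding the confidence in [0, 1] that
the target turns ON in that configuration.  Leaves are indexed with the
lexicographically first regulator as the most significant bit, so for
regulators (A, B) the leaf order is (!A!B, !A B, A !B, A B).

Given M observations with soft regulator states R' (M x N) and soft target
values T' (length M), the fit is a weighted Bayes-style average:

    w_ij = P_j(R'_i)                       leaf membership of observation i
    u_j  = 1 - max_i w_ij                  residual uncertainty of leaf j
    v_j  = (sum_i t'_i w_ij + 0.5 u_j) / (sum_i w_ij + u_j)

P_j is the product over regulators of p (bit set in j) or 1-p, so each
observation's weights over leaves sum to one.  Leaves untouched by data get
v_j = 0.5 exactly; conflicting observations pull v_j back toward 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binarize import BinarizedMatrix
from .io import RegulatoryNetwork

__all__ = [
    "Rule",
    "leaf_probability",
    "leaf_weights",
    "fit_rule",
    "fit_all_rules",
    "predict",
    "cross_validate",
    "CrossValidation",
    "confidence_correlation_curve",
]


@dataclass(frozen=True)
class Rule:
    """Per-target probabilistic truth table with fit diagnostics.

    ``W`` (M x 2^N observation weights) is kept for diagnostics when the
    rule was fitted from data and is ``None`` for constructed or reloaded
    rules; ``U`` is the per-leaf uncertainty."""

    target: str
    regulators: tuple[str, ...]
    V: np.ndarray
    U: np.ndarray
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "U", U)
        n_leaves = 2 ** len(self.regulators)
        if V.shape != (n_leaves,):
            raise ValueError(
                f"rule for {self.target}: V has shape {V.shape}, expected "
                f"({n_leaves},) for {len(self.regulators)} regulators"
            )
        if U.shape != (n_leaves,):
            raise ValueError(f"rule for {self.target}: U has wrong shape")
        if ((V < 0) | (V > 1)).any():
            raise ValueError(f"rule for {self.target}: V entries outside [0, 1]")

    @property
    def n_leaves(self) -> int:
        return self.V.shape[0]


def leaf_weights(state_probs: np.ndarray) -> np.ndarray:
    """Leaf-membership probabilities for soft regulator states.

    ``state_probs`` is (N,) or (M, N); returns (2^N,) or (M, 2^N).  Row sums
    are 1 by construction (the factors (p, 1-p) partition each regulator).
    """
    arr = np.asarray(state_probs, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("state probabilities must lie in [0, 1]")
    m = arr.shape[0]
    w = np.ones((m, 1))
    for col in arr.T:  # first regulator ends up as the most significant bit
        w = (w[:, :, None] * np.stack([1.0 - col, col], axis=-1)[:, None, :]).reshape(
            m, -1
        )
    return w[0] if squeeze else w


def leaf_probability(state_probs: Sequence[float], leaf_index: int) -> float:
    """P_j: probability that soft regulator states fall in leaf ``leaf_index``."""
    arr = np.asarray(state_probs, dtype=float)
    n = arr.shape[0]
    if not 0 <= leaf_index < 2**n:
        raise IndexError(f"leaf index {leaf_index} out of range for {n} regulators")
    bits = (leaf_index >> np.arange(n - 1, -1, -1)) & 1
    return float(np.prod(np.where(bits == 1, arr, 1.0 - arr)))


#: leaves whose total observation weight falls below this are treated as
#: unobserved and pinned to maximal uncertainty (v = 0.5 exactly)
MIN_LEAF_EVIDENCE = 0.01


def fit_rule(
    R_prime: np.ndarray,
    T_prime: np.ndarray,
    regulators: Sequence[str],
    target: str = "",
    min_leaf_evidence: float = MIN_LEAF_EVIDENCE,
) -> Rule:
    """Fit one probabilistic rule from M binarized observations.

    ``R_prime`` (M x N) must have columns in the fixed lexicographic
    regulator order.  M = 0 is allowed and yields maximal uncertainty
    (every v_j = 0.5).

    Leaves whose total weight sum_i w_ij is below ``min_leaf_evidence``
    are pinned to v_j = 0.5 exactly.  Without this floor, a leaf reached
    only through vanishing posterior tails (weights of order 1e-6) would
    carry a vanishing but directional bias away from 0.5, and downstream
    pruning at the 0.5 threshold would treat such unconstrained states as
    confidently stable.  Unconstrained means unconstrained: the dynamics
    there should diffuse.  Set it to 0 to apply the raw weighted average.
    """
    regulators = tuple(regulators)
    n = len(regulators)
    n_leaves = 2**n
    T = np.asarray(T_prime, dtype=float).reshape(-1)
    R = np.asarray(R_prime, dtype=float)
    R = R.reshape(T.shape[0], 0) if n == 0 else R.reshape(-1, n)
    if R.shape[0] != T.shape[0]:
        raise ValueError(
            f"shape mismatch: {R.shape[0]} observations in R', {T.shape[0]} in T'"
        )
    if ((T < 0) | (T > 1)).any():
        raise ValueError("target probabilities must lie in [0, 1]")
    m = R.shape[0]
    if m == 0:
        return Rule(
            target=target,
            regulators=regulators,
            V=np.full(n_leaves, 0.5),
            U=np.ones(n_leaves),
            W=np.zeros((0, n_leaves)),
        )
    W = leaf_weights(R)
    U = 1.0 - W.max(axis=0)
    num = T @ W + 0.5 * U
    den = W.sum(axis=0) + U
    V = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    V = np.clip(V, 0.0, 1.0)  # guard rounding at the boundary
    V[W.sum(axis=0) < min_leaf_evidence] = 0.5
    return Rule(target=target, regulators=regulators, V=V, U=U, W=W)


def fit_all_rules(
    network: RegulatoryNetwork,
    binarized: BinarizedMatrix,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, Rule]:
    """Fit one rule per network node from the binarized matrix.

    ``sample_ids`` restricts the observations (used by cross-validation);
    default is all samples.  Zero-regulator nodes get a single leaf whose
    value is the plain mean of T' (every observation has weight 1, so the
    uncertainty term vanishes).  Self-loops are ordinary inputs.
    """
    probs = binarized.probabilities
    if sample_ids is not None:
        probs = probs[list(sample_ids)]
    missing = [g for g in network.nodes if g not in probs.index]
    if missing:
        raise ValueError(f"network nodes absent from binarized matrix: {missing}")
    rules: dict[str, Rule] = {}
    for target in network.nodes:
        regulators = network.regulators_of(target)
        R = probs.loc[list(regulators)].to_numpy(dtype=float).T
        T = probs.loc[target].to_numpy(dtype=float)
        if len(regulators) == 0:
            R = np.zeros((len(T), 0))
        rules[target] = fit_rule(R, T, regulators, target=target)
    return rules


def predict(rule: Rule, state_probs: Sequence[float]) -> float:
    """Expected rule output under soft regulator states:
    sum_j P_j(state) * v_j, a convex combination of the leaf values."""
    arr = np.asarray(state_probs, dtype=float)
    if arr.shape != (len(rule.regulators),):
        raise ValueError(
            f"expected {len(rule.regulators)} regulator probabilities, "
            f"got shape {arr.shape}"
        )
    return float(leaf_weights(arr) @ rule.V)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossValidation:
    """Split-sample validation output.

    ``per_gene`` holds one row per (iteration, gene) with train/test mean
    squared error; ``pairs`` holds every (prediction, truth) pair with its
    partition; ``correlation_curve`` is the confidence-stratified Pearson
    correlation of test-set predictions vs truths: at window x, only pairs
    with prediction < x or > 1 - x enter.
    """

    per_gene: pd.DataFrame
    pairs: pd.DataFrame
    correlation_curve: pd.DataFrame

    @property
    def train_mse(self) -> float:
        return float(self.per_gene["train_mse"].mean())

    @property
    def test_mse(self) -> float:
        return float(self.per_gene["test_mse"].mean())


def confidence_correlation_curve(
    predictions: np.ndarray,
    truths: np.ndarray,
    grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Pearson correlation restricted to confident predictions.

    For each window x the subset is predictions < x or > 1 - x (x = 0.5
    includes everything).  Windows whose subset is too small or constant
    yield NaN.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    rows = []
    for x in grid:
        mask = (predictions < x) | (predictions > 1.0 - x)
        n = int(mask.sum())
        if n < 3 or np.std(predictions[mask]) == 0 or np.std(truths[mask]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(predictions[mask], truths[mask])[0, 1])
        rows.append({"window": float(x), "correlation": r, "n_pairs": n})
    return pd.DataFrame(rows)


def cross_validate(
    network: RegulatoryNetwork,
    binarized: BinarizedMatrix,
    train_fraction: float = 0.8,
    iterations: int = 70,
    seed: int = 0,
) -> CrossValidation:
    """Repeated random-split validation of the fitted rules.

    Per iteration the samples are split (floor(train_fraction * M) train,
    rest test, drawn without replacement), rules are fit on the training
    partition, and squared prediction error against the binarized target
    values is averaged per gene on both partitions.
    """
    samples = binarized.sample_ids
    m = len(samples)
    if m < 5:
        raise ValueError("need at least 5 samples for split validation")
    n_train = int(np.floor(train_fraction * m))
    if n_train < 1 or n_train >= m:
        raise ValueError("train_fraction leaves an empty partition")
    rng = np.random.default_rng(seed)
    probs = binarized.probabilities
    gene_rows, pair_rows = [], []
    for it in range(iterations):
        perm = rng.permutation(m)
        train = [samples[i] for i in perm[:n_train]]
        test = [samples[i] for i in perm[n_train:]]
        rules = fit_all_rules(network, binarized, sample_ids=train)
        for target, rule in rules.items():
            regulators = list(rule.regulators)
            for part, ids in (("train", train), ("test", test)):
                R = probs.loc[regulators, ids].to_numpy(dtype=float).T
                truth = probs.loc[target, ids].to_numpy(dtype=float)
                pred = leaf_weights(R) @ rule.V if regulators else np.full(
                    len(ids), rule.V[0]
                )
                err = (pred - truth) ** 2
                gene_rows.append(
                    {
                        "iteration": it,
                        "gene": target,
                        "partition": part,
                        "mse": float(err.mean()),
                    }
                )
                pair_rows.extend(
                    {
                        "iteration": it,
                        "gene": target,
                        "partition": part,
                        "prediction": float(p),
                        "truth": float(t),
                    }
                    for p, t in zip(pred, truth)
                )
    long = pd.DataFrame(gene_rows)
    per_gene = (
        long.pivot_table(
            index=["iteration", "gene"], columns="partition", values="mse"
        )
        .rename(columns={"train": "train_mse", "test": "test_mse"})
        .reset_index()
    )
    per_gene.columns.name = None
    pairs = pd.DataFrame(pair_rows)
    test_pairs = pairs[pairs["partition"] == "test"]
    curve = confidence_correlation_curve(
        test_pairs["prediction"].to_numpy(), test_pairs["truth"].to_numpy()
    )
    return CrossValidation(per_gene=per_gene, pairs=pairs, correlation_curve=curve)
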
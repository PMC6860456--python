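"""In-silico perturbation stability analysis.

Starting from a pseudo-attractor, a random walk repeatedly applies
general-asynchronous updates until the state drifts more than
``escape_radius`` TF changes from the start; the number of update events
(including non-flipping ones) measures how stable the attractor is.  A
perturbation holds one TF OFF (knockdown) or ON (activation) throughout the
walk; its stability score is the fractional change of the mean escape time
relative to unperturbed walks from the same start:

    score = (mean_steps - reference_mean_steps) / reference_mean_steps

A TF whose knockdown drops a subtype's score to -0.2 or below is a master
regulator of that subtype; one whose activation does is a master
destabilizer.  Escape distance is Hamming distance to the perturbation-
modified start state, so the held TF never consumes escape budget.

Each (start, perturbation) condition runs on its own logged RNG sub-stream,
making every condition reproducible independently of execution order.  For
small networks :func:`expected_escape_steps` solves the absorbing Markov
chain exactly, which the Monte Carlo walks can be checked against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import PseudoAttractor
from .dynamics import Dynamics, State, hamming, state_to_str
from .io import WalkConfig
from .rules import Rule

__all__ = [
    "Perturbation",
    "StabilityResult",
    "random_walk",
    "stability_score",
    "scan_perturbations",
    "cluster_scores",
    "classify_masters",
    "expected_escape_steps",
]

MODES = ("knockdown", "activation", "none")


@dataclass(frozen=True)
class Perturbation:
    """A TF held at a constant value: knockdown holds 0, activation holds 1,
    mode ``none`` is the unperturbed reference."""

    tf: str | None = None
    mode: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown perturbation mode '{self.mode}'")
        if self.mode != "none" and self.tf is None:
            raise ValueError("perturbation needs a target TF")

    @property
    def held_value(self) -> int | None:
        if self.mode == "knockdown":
            return 0
        if self.mode == "activation":
            return 1
        return None

    def label(self) -> str:
        return f"{self.tf or '-'}|{self.mode}"


@dataclass(frozen=True)
class StabilityResult:
    """Escape-step statistics for one (start, perturbation) condition."""

    start: State
    perturbation: Perturbation
    steps: np.ndarray
    reference_mean_steps: float
    n_censored: int
    seed: int
    cluster: str | None = None

    @property
    def mean_steps(self) -> float:
        return float(np.mean(self.steps))

    @property
    def n_walks(self) -> int:
        return int(len(self.steps))

    @property
    def score(self) -> float:
        """Fractional change of mean escape time vs the unperturbed walks."""
        return float(
            (self.mean_steps - self.reference_mean_steps) / self.reference_mean_steps
        )

    def histogram(self) -> pd.DataFrame:
        """Steps-to-escape histogram (one row per distinct step count)."""
        vals, counts = np.unique(self.steps, return_counts=True)
        return pd.DataFrame({"steps": vals, "count": counts})


def _prepare_start(
    dyn: Dynamics, start: Sequence[int], perturbation: Perturbation
) -> tuple[State, tuple[str, ...]]:
    state = list(int(b) for b in start)
    if len(state) != dyn.g:
        raise ValueError(f"start state has length {len(state)}, expected {dyn.g}")
    fixed: tuple[str, ...] = ()
    if perturbation.mode != "none":
        if perturbation.tf not in dyn.index:
            raise KeyError(f"unknown TF '{perturbation.tf}'")
        state[dyn.index[perturbation.tf]] = perturbation.held_value
        fixed = (perturbation.tf,)
    return tuple(state), fixed


def _walk(
    dyn: Dynamics,
    start: State,
    fixed: tuple[str, ...],
    config: WalkConfig,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    n_free = dyn.g - len(fixed)
    if config.escape_radius >= n_free:
        raise ValueError(
            f"escape_radius {config.escape_radius} >= {n_free} free TFs; "
            f"escape is impossible"
        )
    fixed_idx = {dyn.index[t] for t in fixed}
    free = [i for i in range(dyn.g) if i not in fixed_idx]
    tables = dyn._tables
    state = list(start)
    dist = 0
    steps = 0
    while dist <= config.escape_radius:
        if steps >= config.max_steps:
            return steps, True
        steps += 1
        i = free[int(rng.integers(n_free))]
        r = rng.random()
        p_on = tables[i][dyn._leaf_index(state, i)]
        p_flip = p_on if state[i] == 0 else 1.0 - p_on
        if r < p_flip:
            state[i] = 1 - state[i]
            dist += 1 if state[i] != start[i] else -1
    return steps, False


def random_walk(
    rules: Dynamics | Mapping[str, Rule],
    start: Sequence[int],
    perturbation: Perturbation = Perturbation(),
    config: WalkConfig = WalkConfig(),
    rng: np.random.Generator | None = None,
) -> int:
    """One random walk; returns the number of update events taken before the
    Hamming distance from the (perturbation-modified) start first exceeds
    ``config.escape_radius``, or ``config.max_steps`` if censored."""
    dyn = Dynamics.ensure(rules)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    start_mod, fixed = _prepare_start(dyn, start, perturbation)
    steps, _ = _walk(dyn, start_mod, fixed, config, rng)
    return steps


def _condition_rng(seed: int, start: State, perturbation: Perturbation,
                   reference: bool = False) -> tuple[np.random.Generator, int]:
    tag = f"{state_to_str(start)}|{perturbation.label()}|{'ref' if reference else 'cond'}"
    key = zlib.crc32(tag.encode())
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.default_rng(ss), key


def _run_condition(
    dyn: Dynamics,
    start: Sequence[int],
    perturbation: Perturbation,
    config: WalkConfig,
    reference: bool = False,
) -> tuple[np.ndarray, int]:
    start_mod, fixed = _prepare_start(dyn, start, perturbation)
    rng, _ = _condition_rng(config.seed, tuple(int(b) for b in start),
                            perturbation, reference)
    steps = np.empty(config.n_walks, dtype=int)
    censored = 0
    for k in range(config.n_walks):
        steps[k], c = _walk(dyn, start_mod, fixed, config, rng)
        censored += int(c)
    return steps, censored


def stability_score(
    rules: Dynamics | Mapping[str, Rule],
    start: Sequence[int] | PseudoAttractor,
    perturbation: Perturbation,
    config: WalkConfig = WalkConfig(),
) -> StabilityResult:
    """Monte Carlo stability score of one perturbation at one attractor.

    Runs ``config.n_walks`` unperturbed reference walks and the same number
    of perturbed walks on independent seeded sub-streams, and reports the
    fractional change of mean escape steps.
    """
    dyn = Dynamics.ensure(rules)
    cluster = None
    if isinstance(start, PseudoAttractor):
        cluster = start.cluster
        start = start.representative
    ref_steps, _ = _run_condition(dyn, start, Perturbation(), config, reference=True)
    steps, censored = _run_condition(dyn, start, perturbation, config)
    return StabilityResult(
        start=tuple(int(b) for b in start),
        perturbation=perturbation,
        steps=steps,
        reference_mean_steps=float(ref_steps.mean()),
        n_censored=censored,
        seed=config.seed,
        cluster=cluster,
    )


def scan_perturbations(
    rules: Dynamics | Mapping[str, Rule],
    attractors: Iterable[PseudoAttractor],
    config: WalkConfig = WalkConfig(),
) -> list[StabilityResult]:
    """Score knockdown and activation of every TF at every attractor.

    Per attractor: one shared unperturbed reference condition plus 2 * g
    perturbed conditions, each on its own RNG sub-stream.  The reference is
    included in the output as a mode-``none`` row (score 0 by definition).
    """
    dyn = Dynamics.ensure(rules)
    attractors = list(attractors)
    if not attractors:
        raise ValueError("need at least one attractor to perturb")
    results: list[StabilityResult] = []
    for att in attractors:
        start = att.representative
        ref_steps, ref_censored = _run_condition(
            dyn, start, Perturbation(), config, reference=True
        )
        ref_mean = float(ref_steps.mean())
        results.append(
            StabilityResult(
                start=start,
                perturbation=Perturbation(),
                steps=ref_steps,
                reference_mean_steps=ref_mean,
                n_censored=ref_censored,
                seed=config.seed,
                cluster=att.cluster,
            )
        )
        for tf in dyn.nodes:
            for mode in ("knockdown", "activation"):
                pert = Perturbation(tf=tf, mode=mode)
                steps, censored = _run_condition(dyn, start, pert, config)
                results.append(
                    StabilityResult(
                        start=start,
                        perturbation=pert,
                        steps=steps,
                        reference_mean_steps=ref_mean,
                        n_censored=censored,
                        seed=config.seed,
                        cluster=att.cluster,
                    )
                )
    return results


def cluster_scores(results: Iterable[StabilityResult]) -> pd.DataFrame:
    """Per-cluster perturbation scores: the unweighted mean of the score
    over that cluster's attractors, one row per (cluster, tf, mode)."""
    rows = [
        {
            "cluster": res.cluster,
            "tf": res.perturbation.tf,
            "mode": res.perturbation.mode,
            "score": res.score,
        }
        for res in results
        if res.perturbation.mode != "none"
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["cluster", "tf", "mode"], dropna=False)["score"]
        .mean()
        .reset_index()
    )


def classify_masters(
    scores: pd.DataFrame, threshold: float = -0.2
) -> dict[str, dict[str, set[str]]]:
    """Classify TFs per cluster from aggregated scores.

    Knockdown score <= ``threshold`` makes a TF a master regulator of the
    cluster; activation score <= ``threshold`` a master destabilizer.  A TF
    may appear for several clusters.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for _, row in scores.iterrows():
        cluster = row["cluster"]
        entry = out.setdefault(
            cluster, {"master_regulators": set(), "master_destabilizers": set()}
        )
        if row["score"] <= threshold:
            if row["mode"] == "knockdown":
                entry["master_regulators"].add(row["tf"])
            elif row["mode"] == "activation":
                entry["master_destabilizers"].add(row["tf"])
    return out


def expected_escape_steps(
    rules: Dynamics | Mapping[str, Rule],
    start: Sequence[int],
    perturbation: Perturbation = Perturbation(),
    escape_radius: int = 4,
    max_nodes: int = 14,
) -> float:
    """Exact expected escape time from the absorbing-Markov-chain solve.

    Enumerates the reachable state space (the subspace with the held TF at
    its clamped value), treats every state farther than ``escape_radius``
    from the modified start as absorbing, and solves (I - Q) E = 1 for the
    expected number of update events until absorption.  Intended for small
    networks (g <= ``max_nodes``); walks with a step cap are slightly
    below this value when censoring occurs.
    """
    dyn = Dynamics.ensure(rules)
    if dyn.g > max_nodes:
        raise ValueError(f"exact solve limited to g <= {max_nodes} nodes")
    start_mod, fixed = _prepare_start(dyn, start, perturbation)
    fixed_idx = {dyn.index[t] for t in fixed}
    free = [i for i in range(dyn.g) if i not in fixed_idx]
    n_free = len(free)
    if escape_radius >= n_free:
        raise ValueError("escape_radius >= number of free TFs; escape impossible")

    # enumerate the subspace: free bits vary, fixed bits stay clamped
    states: list[State] = []
    for code in range(2**n_free):
        s = list(start_mod)
        for k, i in enumerate(free):
            s[i] = (code >> k) & 1
        states.append(tuple(s))
    in_bounds = [s for s in states if hamming(s, start_mod) <= escape_radius]
    index = {s: k for k, s in enumerate(in_bounds)}
    n = len(in_bounds)
    Q = np.zeros((n, n))
    for s, k in index.items():
        stay = 1.0
        for i in free:
            p_on = dyn._tables[i][dyn._leaf_index(s, i)]
            p_flip = p_on if s[i] == 0 else 1.0 - p_on
            p = p_flip / n_free
            stay -= p
            t = list(s)
            t[i] = 1 - t[i]
            t = tuple(t)
            if t in index:
                Q[k, index[t]] += p
        Q[k, k] += stay
    E = np.linalg.solve(np.eye(n) - Q, np.ones(n))
    return float(E[index[start_mod]])
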
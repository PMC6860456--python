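# Methods

This note documents the models and procedures implemented in `boolbayes`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data experiments do and do not demonstrate.

## Binarization

Each gene is treated as an independent 1-D two-component Gaussian mixture
across samples. The binarized value of a sample is the posterior
probability of the larger-mean ("ON") component at that sample's
expression level.

Choices and rationale:

- **Tied variance.** The two components share one variance, which makes
  the ON posterior a logistic (hence monotone) function of expression. With
  free variances the posterior of the high-mean component can become
  non-monotone in the tails, i.e. very high expression could be called
  "probably OFF" — biologically nonsensical for this use.
- **Initialisation and convergence.** Component means start at the 25th and
  75th percentiles, weights at 0.5/0.5; EM runs to tolerance 1e-6 with at
  most 500 iterations and a fixed `random_state`, so refits are
  bit-reproducible.
- **Degeneracy.** If a gene's total variance is below 1e-12 or the fitted
  means separate by less than 1e-3 sample standard deviations, the gene is
  flagged degenerate and every posterior is set to exactly 0.5. An
  uninformative gene should not make hard calls.

Expression is accepted as already normalized (log-scale, non-negative,
e.g. log1p TPM); the package validates but never renormalizes.

## Rule fitting

For a target with N regulators (fixed lexicographic order; the first
regulator is the most significant bit of the leaf index), the rule vector
V over the 2^N leaves is the uncertainty-blended weighted average described
in the README: observation i supports leaf j with weight
w_ij = Π_k (r′_ik or 1−r′_ik), each leaf carries uncertainty
u_j = 1 − max_i w_ij, and v_j averages the binarized target values under
those weights with the u_j mass pulled toward 0.5.

- **Leaves with no data are exactly 0.5**, and leaves whose *total* weight
  Σ_i w_ij falls below `MIN_LEAF_EVIDENCE = 0.01` (one hundredth of a
  single observation) are pinned to exactly 0.5 as well. This floor is a
  numerical tie-break with real consequences: when binarized posteriors
  saturate, far-from-data leaves receive vanishing (1e-6 … 1e-16) but
  directional weights, and the strict `< 0.5` pruning rule downstream would
  otherwise certify entirely unconstrained states as stable. The intent of
  the uncertainty construction is that unconstrained regions of state space
  diffuse randomly; the floor enforces that intent under floating point.
  Set `min_leaf_evidence=0` in `fit_rule` for the raw formulas.
- **Zero-regulator nodes** are the formula's natural N = 0 limit: a single
  leaf on which every observation has weight 1, so u = 0 and v is the plain
  mean of the binarized target values.
- **Self-loops** are ordinary inputs: a target's own binarized value
  participates in its regulator state.
- **Prediction** (used in validation) is the leaf-probability-weighted
  expectation Σ_j P_j(state) · v_j — the only estimator consistent with the
  leaf decomposition.
- Network edge signs, if present, are carried through for reporting and
  for the baseline schemes below; the probabilistic fit is unsigned.
- The in-degree cap (default 20) is a hard error: V is dense with 2^N
  entries, and the method's premise is a sparse network.

## Dynamics and pseudo-attractors

Updates are general-asynchronous: one non-fixed TF chosen uniformly per
event, flipped with probability `p_on` (if OFF) or `1 − p_on` (if ON). The
bounded state-transition graph around an initial state explores the
Hamming ball of radius R (default 6 TF changes): in-bounds states carry one
out-edge per TF weighted by its flip probability; states beyond the radius
point to an out-of-bounds sink with weight 1, so nothing that escapes the
ball can masquerade as stable. Self-transitions are implicit.

Pseudo-attractors are the strongly connected components of the pruned
graph (edges with flip probability strictly below P_T = 0.5 removed) that
contain no sink and have no retained out-edge. The strictness matters: a
flip probability of exactly 0.5 retains its edge, so a state held only at
coin-flip odds is not called stable. Search radii larger than the node
count are clamped to it (Hamming distances cannot exceed g).

Initial states come from discretized cluster means (per-TF mean
ON-probability thresholded at 0.5, ties to OFF), supplemented by a sweep
of uniform random initial states (default 200) to guard against attractors
far from the data. Attractors are assigned to clusters by minimum Hamming
distance from the representative state (lexicographically smallest member)
to each cluster's discretized mean; ties go to the alphabetically first
cluster and are flagged ambiguous rather than resolved silently. The
assignment metric is recorded in run metadata because correlation-based
assignment is an equally defensible choice.

Two deterministic baseline schemes are provided for comparison on signed
networks: *inhibitory dominant* (ON iff at least one activator is ON and
all inhibitors are OFF) and *majority* (ON iff strictly more activators
than inhibitors are ON).

## Perturbation stability

A perturbation holds one TF at 0 (knockdown) or 1 (activation). Walks
start from the perturbation-modified attractor state, so the held TF
contributes nothing to escape distance; each update event increments the
step counter whether or not the coin flips. A walk ends when the Hamming
distance from the modified start exceeds `escape_radius` (default 4,
chosen to tolerate intra-phenotype drift) or at the step cap (default
5000). Censored walks are counted at the cap and reported — without a cap,
a deterministic attractor would never terminate. The stability score is
`(mean − reference_mean) / reference_mean` over `n_walks` (default 1000)
per condition; knockdown scores ≤ −0.2 define master regulators, activation
scores ≤ −0.2 master destabilizers of a cluster, with per-cluster scores
the unweighted mean over that cluster's attractors.

Every (start, perturbation) condition draws from its own RNG sub-stream,
keyed by a CRC of the condition label under the top-level seed, so
conditions are reproducible individually and independent of execution
order.

For networks of ≤ 14 nodes, `expected_escape_steps` computes the exact
expected escape time by solving the absorbing-Markov-chain linear system
(I − Q)E = 1 over the in-bounds states of the clamped subspace. The test
suite holds Monte-Carlo means to within 3 standard errors of these exact
values. One caveat: the escape criterion is Hamming distance from the
start, not shortest-path distance in the STG; with single-TF updates the
two coincide step-for-step in expectation, and the Hamming reading is the
one consistent with the walk's termination rule.

## Synthetic data

The generator emulates the intended study design: a small TF network whose
fixed-point attractors are observed as clusters of steady-state samples.
Defaults are 12 nodes, in-degree ≤ 3, 4 attractor-clusters, 12
samples/cluster, μ_off = 1, μ_on = 6, σ = 0.5 (expression truncated at 0
by redraw). The 10σ gap between component means makes binarization
near-deterministic, isolating the behavior of rule fitting and attractor
search; σ = 1.5 is used where the uncertain regime itself is under test
(e.g. the confidence-stratified validation curve).

Random networks are resampled until exhaustive enumeration (feasible to 12
nodes) finds exactly the requested number of fixed points *and* every gene
differs between at least two of them. The marker requirement mirrors how
such networks are assembled in practice — from TFs differentially expressed
across the phenotypes — and is a genuine limitation of per-gene two-component
binarization: a gene constant across all clusters is unimodal in
expression, and its mixture fit conveys no ON/OFF signal.

What passing the recovery experiment shows: on well-separated data from a
network whose attractors the clusters represent faithfully, the pipeline
returns exactly the generating attractors with correctly fitted rules on
data-covered leaves. What it does not show: robustness to mis-specified
network structure, to clusters that are not attractors, to strongly
imbalanced cluster sizes, or to real RNA-seq features (library-size
variation, overdispersion, dropout) — the generator deliberately models
none of these.

## Known limitations

- Rules are fitted per target independently; the method never enforces
  global consistency, and inferred stability is only as good as the input
  edge list.
- Multi-state pseudo-attractors are summarized by their lexicographically
  smallest state for walks and assignment; for long cycles a
  trajectory-aware summary might differ.
- Perturbations are single-TF and binary; combinatorial or dose-like
  partial clamps are out of scope.
- The bounded search can only find attractors within the search radius of
  some initial state; the random-restart sweep mitigates but cannot
  eliminate this.
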
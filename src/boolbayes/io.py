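"""Input/output for the standard artifacts and shared run configuration.

The tool consumes three plain-text inputs:

* an expression matrix (TSV/CSV; first column gene ids, header row sample
  ids; log-scale, non-negative values such as log1p TPM),
* a directed regulator->target edge list (TSV ``source<TAB>target[<TAB>sign]``
  with sign one of ``+``, ``-``, ``?``),
* optional sample->cluster labels (CSV ``sample,cluster``).

Expression is accepted as already normalized; no normalization is performed
beyond validation.  Regulator order for every target is fixed lexicographic
so that rule-leaf indexing is deterministic across runs.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "RegulatoryNetwork",
    "ClusterLabels",
    "SearchConfig",
    "WalkConfig",
    "load_expression",
    "load_network",
    "load_labels",
    "load_inputs",
    "export_rules",
    "read_rules",
    "export_attractors",
    "read_attractors",
    "export_scores",
    "load_config",
    "save_config",
    "file_digest",
]

VALID_SIGNS = ("+", "-", "?")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative log-scale expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if df.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed TF network: nodes, signed edges, and a per-target regulator
    order (lexicographic) used for rule-leaf indexing.

    Edge signs are carried through for reporting and for the baseline
    deterministic update schemes; probabilistic rule inference is unsigned.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]
    in_degree_cap: int = 20

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.nodes))) != self.nodes:
            object.__setattr__(self, "nodes", tuple(sorted(set(self.nodes))))
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign in self.edges:
            if src not in node_set:
                raise ValueError(f"unknown node '{src}' in edge list")
            if tgt not in node_set:
                raise ValueError(f"unknown node '{tgt}' in edge list")
            if sign not in VALID_SIGNS:
                raise ValueError(f"invalid edge sign '{sign}' (expect +, - or ?)")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge {src}->{tgt}")
            seen.add((src, tgt))
        for node in self.nodes:
            n_in = len(self.regulators_of(node))
            if n_in > self.in_degree_cap:
                raise ValueError(
                    f"in-degree of '{node}' is {n_in}, above the cap of "
                    f"{self.in_degree_cap} (rule tables are dense with "
                    f"2^in-degree leaves)"
                )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str] | tuple[str, str]],
        nodes: Iterable[str] = (),
        in_degree_cap: int = 20,
    ) -> "RegulatoryNetwork":
        """Build a network, deduplicating repeated (regulator, target) rows
        with a warning. Two-tuples get sign ``?``."""
        node_set = set(nodes)
        unique: dict[tuple[str, str], str] = {}
        for edge in edges:
            if len(edge) == 2:
                src, tgt = edge  # type: ignore[misc]
                sign = "?"
            else:
                src, tgt, sign = edge  # type: ignore[misc]
            if (src, tgt) in unique:
                warnings.warn(f"duplicate edge {src}->{tgt} dropped", stacklevel=2)
                continue
            unique[(src, tgt)] = sign
            node_set.update((src, tgt))
        return cls(
            nodes=tuple(sorted(node_set)),
            edges=tuple((s, t, g) for (s, t), g in sorted(unique.items())),
            in_degree_cap=in_degree_cap,
        )

    @property
    def g(self) -> int:
        return len(self.nodes)

    def regulators_of(self, target: str) -> tuple[str, ...]:
        """Regulators of ``target`` in the fixed lexicographic order; the
        first regulator is the most significant bit of the leaf index."""
        return tuple(sorted(src for src, tgt, _ in self.edges if tgt == target))

    def signed_regulators_of(self, target: str) -> tuple[tuple[str, str], ...]:
        by_src = {src: sign for src, tgt, sign in self.edges if tgt == target}
        return tuple((src, by_src[src]) for src in sorted(by_src))


@dataclass(frozen=True)
class ClusterLabels:
    """Sample -> cluster label mapping (small finite label set)."""

    mapping: Mapping[str, str]

    @property
    def clusters(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def samples_in(self, cluster: str) -> list[str]:
        return [s for s, c in self.mapping.items() if c == cluster]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.sample_ids)
        missing = sorted(set(self.mapping) - known)
        if missing:
            raise ValueError(f"labeled samples absent from matrix: {missing}")
        for cluster in self.clusters:
            if not self.samples_in(cluster):
                raise ValueError(f"cluster '{cluster}' has no samples")


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the bounded pseudo-attractor search.

    ``radius`` is the Hamming neighborhood explored around each initial
    state (default 6 TF changes); ``threshold`` is the edge-pruning cutoff
    P_T on flip probabilities (default 0.5, strict: edges with weight
    exactly P_T are retained); ``n_random_starts`` controls the random
    restart sweep.
    """

    radius: int = 6
    threshold: float = 0.5
    n_random_starts: int = 200
    in_degree_cap: int = 20
    seed: int = 0
    max_vertices: int = 2_000_000

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.n_random_starts < 0:
            raise ValueError("n_random_starts must be non-negative")


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the random-walk stability assay: walks escape when the
    Hamming distance from the start state exceeds ``escape_radius``
    (default 4 TFs); ``n_walks`` per condition (default 1000); walks are
    censored at ``max_steps``."""

    escape_radius: int = 4
    n_walks: int = 1000
    max_steps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.escape_radius < 0:
            raise ValueError("escape_radius must be non-negative")
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample expression table (TSV or CSV by extension)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed expression file {path.name}: {exc}") from exc
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ValueError(
            f"non-numeric expression columns in {path.name}: {non_numeric}"
        )
    return ExpressionMatrix(df)


def load_network(path: str | Path, in_degree_cap: int = 20) -> RegulatoryNetwork:
    """Read a ``source<TAB>target[<TAB>sign]`` edge list."""
    path = Path(path)
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 2 or cols[0].lower() not in {"source", "regulator"}:
            raise ValueError(
                f"{path.name}:1: expected header 'source<TAB>target[<TAB>sign]'"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 or 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            sign = parts[2].strip() if len(parts) == 3 else "?"
            if sign not in VALID_SIGNS:
                raise ValueError(
                    f"{path.name}:{lineno}: invalid sign '{sign}' (use +, - or ?)"
                )
            edges.append((parts[0].strip(), parts[1].strip(), sign))
    return RegulatoryNetwork.from_edges(edges, in_degree_cap=in_degree_cap)


def load_labels(path: str | Path) -> ClusterLabels:
    """Read a ``sample,cluster`` CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", dtype=str)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed labels file {path.name}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected columns 'sample,cluster'")
    sample_col, cluster_col = df.columns[:2]
    mapping = dict(zip(df[sample_col].astype(str), df[cluster_col].astype(str)))
    if len(mapping) != len(df):
        raise ValueError(f"{path.name}: duplicate sample labels")
    return ClusterLabels(mapping)


def load_inputs(
    expression_path: str | Path,
    network_path: str | Path,
    labels_path: str | Path | None = None,
    in_degree_cap: int = 20,
) -> tuple[ExpressionMatrix, RegulatoryNetwork, ClusterLabels | None]:
    """Load and cross-validate the three standard inputs.

    Every network node must appear in the expression matrix (error names
    the missing gene), and every labeled sample must exist in the matrix.
    """
    matrix = load_expression(expression_path)
    network = load_network(network_path, in_degree_cap=in_degree_cap)
    known_genes = set(matrix.gene_ids)
    for node in network.nodes:
        if node not in known_genes:
            raise ValueError(
                f"unknown node '{node}': present in network but not in the "
                f"expression matrix"
            )
    labels = None
    if labels_path is not None:
        labels = load_labels(labels_path)
        labels.validate_against(matrix)
    return matrix, network, labels


# ---------------------------------------------------------------------------
# exporting (decimal text round-trips bit-identically via %.17g)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def export_rules(rules: Mapping[str, "object"], out_dir: str | Path) -> list[Path]:
    """Write one CSV per target: 2^N rows of binary regulator states plus
    columns ``v``, ``u``, ``n_effective`` (sum of observation weights)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for target in sorted(rules):
        rule = rules[target]
        n = len(rule.regulators)
        leaves = np.arange(2**n)
        data = {
            reg: (leaves >> (n - 1 - k)) & 1 for k, reg in enumerate(rule.regulators)
        }
        data["v"] = rule.V
        data["u"] = rule.U
        data["n_effective"] = (
            rule.W.sum(axis=0) if rule.W is not None else np.zeros(2**n)
        )
        path = out_dir / f"rule_{target}.csv"
        pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    return written


def read_rules(in_dir: str | Path) -> dict[str, "object"]:
    """Reload rules written by :func:`export_rules` (W is not persisted)."""
    from .rules import Rule

    in_dir = Path(in_dir)
    rules: dict[str, Rule] = {}
    for path in sorted(in_dir.glob("rule_*.csv")):
        target = path.stem[len("rule_") :]
        df = pd.read_csv(path, float_precision="round_trip")
        regulators = tuple(c for c in df.columns if c not in ("v", "u", "n_effective"))
        rules[target] = Rule(
            target=target,
            regulators=regulators,
            V=df["v"].to_numpy(dtype=float),
            U=df["u"].to_numpy(dtype=float),
            W=None,
        )
    return rules


def export_attractors(
    attractors: Sequence["object"],
    nodes: Sequence[str],
    out_path: str | Path,
) -> Path:
    """Write attractors as CSV: one row per member state with binary TF
    columns, attractor id, SCC size, assigned cluster, ambiguity flag and
    Hamming distance to each cluster reference."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    cluster_names = sorted(
        {c for a in attractors for c in (a.distances or {})}
    )
    rows = []
    for aid, att in enumerate(attractors):
        for state in sorted(att.states):
            row: dict[str, object] = {n: b for n, b in zip(nodes, state)}
            row["attractor_id"] = aid
            row["scc_size"] = len(att.states)
            row["representative"] = "".join(map(str, att.representative))
            row["cluster"] = att.cluster if att.cluster is not None else ""
            row["ambiguous"] = bool(att.ambiguous)
            for c in cluster_names:
                row[f"dist_{c}"] = att.distances[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path


def read_attractors(path: str | Path, nodes: Sequence[str]) -> list["object"]:
    from .attractors import PseudoAttractor

    df = pd.read_csv(path, keep_default_na=False)
    dist_cols = [c for c in df.columns if c.startswith("dist_")]
    out = []
    for aid, grp in df.groupby("attractor_id"):
        states = frozenset(
            tuple(int(row[n]) for n in nodes) for _, row in grp.iterrows()
        )
        first = grp.iloc[0]
        distances = {c[len("dist_") :]: int(first[c]) for c in dist_cols}
        cluster = str(first["cluster"]) or None
        out.append(
            PseudoAttractor(
                states=states,
                cluster=cluster,
                ambiguous=bool(first["ambiguous"]),
                distances=distances or None,
            )
        )
    return out


def export_scores(results: Sequence["object"], out_path: str | Path) -> Path:
    """Write stability results as CSV
    ``tf,mode,start_attractor,cluster,mean_steps,reference_mean_steps,score,n_walks,seed``."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        rows.append(
            {
                "tf": res.perturbation.tf or "",
                "mode": res.perturbation.mode,
                "start_attractor": "".join(map(str, res.start)),
                "cluster": res.cluster or "",
                "mean_steps": res.mean_steps,
                "reference_mean_steps": res.reference_mean_steps,
                "score": res.score,
                "n_walks": res.n_walks,
                "seed": res.seed,
                "n_censored": res.n_censored,
            }
        )
    pd.DataFrame(rows).to_csv(out_path, index=False, float_format=_FLOAT_FMT)
    return out_path


def load_config(path: str | Path) -> dict:
    """Read a ``key: value`` YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key: value mapping")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, recorded in run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
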
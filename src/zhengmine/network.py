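"""Symptom association networks from binary four-diagnostic records.

Association strength between two symptoms is the empirical mutual
information (in bits) of their patient-level co-occurrence. Edges are
selected either by a fixed edge budget (the m strongest pairs; the reference
network keeps 120 edges among 69 symptoms) or by a permutation significance
gate. The resulting undirected graph interoperates with the Pajek ``.net``
format and exposes a symmetric 0/1 adjacency-matrix view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationEdge:
    symptom_a: str
    symptom_b: str
    mi: float
    p_perm: float | None = None

    def __post_init__(self) -> None:
        if self.symptom_a == self.symptom_b:
            raise ValueError(f"self-loop on {self.symptom_a!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.symptom_a, self.symptom_b)))


@dataclass
class AssociationNetwork:
    """Undirected symptom graph; no self-loops, no parallel edges."""

    nodes: list[str]
    edges: list[AssociationEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        seen = set()
        for e in self.edges:
            if e.symptom_a not in node_set or e.symptom_b not in node_set:
                raise ValueError(f"edge endpoint not in nodes: {e.pair}")
            if e.pair in seen:
                raise ValueError(f"parallel edge: {e.pair}")
            seen.add(e.pair)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def adjacency_matrix(self) -> pd.DataFrame:
        """Symmetric 0/1 adjacency with zero diagonal, node order preserved."""
        idx = {v: i for i, v in enumerate(self.nodes)}
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for e in self.edges:
            i, j = idx[e.symptom_a], idx[e.symptom_b]
            a[i, j] = a[j, i] = 1
        return pd.DataFrame(a, index=self.nodes, columns=self.nodes)

    def subgraph(self, keep: list[str]) -> "AssociationNetwork":
        keep_set = set(keep)
        return AssociationNetwork(
            nodes=[v for v in self.nodes if v in keep_set],
            edges=[
                e for e in self.edges
                if e.symptom_a in keep_set and e.symptom_b in keep_set
            ],
        )


@dataclass(frozen=True)
class NetworkConfig:
    """Edge selection: exactly one of edge_budget / alpha_perm is active."""

    edge_budget: int | None = 120
    alpha_perm: float | None = None
    n_permutations: int = 999
    random_seed: int = 0

    def __post_init__(self) -> None:
        if (self.edge_budget is None) == (self.alpha_perm is None):
            raise ConfigurationError(
                "exactly one of edge_budget and alpha_perm must be set"
            )
        if self.edge_budget is not None and self.edge_budget < 1:
            raise ConfigurationError("edge_budget must be >= 1")
        if self.alpha_perm is not None and not 0 < self.alpha_perm <= 1:
            raise ConfigurationError("alpha_perm must be in (0, 1]")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")


def pairwise_mutual_information(x, y) -> float:
    """Mutual information in bits between two binary vectors.

    MI = sum over the four joint cells of p(a,b) log2(p(a,b)/(p(a)p(b)));
    empty cells contribute zero. Symmetric and nonnegative.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n11 = int(np.sum((x == 1) & (y == 1)))
    kx = int(np.sum(x == 1))
    ky = int(np.sum(y == 1))
    return _mi_from_margins(np.array(n11), kx, ky, x.size).item()


def _mi_from_margins(n11, kx: int, ky: int, n: int):
    """Vectorized MI (bits) of 2x2 tables given n11 and fixed margins."""
    n11 = np.atleast_1d(np.asarray(n11, dtype=float))
    cells = np.stack(
        [n - kx - ky + n11, ky - n11, kx - n11, n11]
    )  # joint counts for (0,0), (0,1), (1,0), (1,1)
    px = np.array([n - kx, n - kx, kx, kx], dtype=float)[:, None] / n
    py = np.array([n - ky, ky, n - ky, ky], dtype=float)[:, None] / n
    pab = cells / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pab * np.log2(pab / (px * py))
    terms = np.where(pab > 0, terms, 0.0)
    return np.maximum(terms.sum(axis=0), 0.0)


def _joint_counts(x01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs 1-1 co-occurrence counts and per-column 1-counts."""
    xf = x01.astype(np.float64)
    return (xf.T @ xf).round().astype(np.int64), x01.sum(axis=0).astype(np.int64)


def build_association_network(
    cohort: Cohort, config: NetworkConfig
) -> AssociationNetwork:
    """Screen all symptom pairs by mutual information.

    Constant symptom columns (all 0 or all 1) are dropped with a warning —
    they carry no information and break the permutation null. In edge-budget
    mode the m highest-MI pairs are kept, ties at the boundary broken
    lexicographically by pair name; in permutation mode pairs significant
    under label shuffling at alpha_perm are kept. Since MI of a 2x2 table
    depends on the joint counts only, the shuffled null is sampled exactly
    as hypergeometric draws of the 1-1 cell with fixed margins.
    """
    symptoms = cohort.symptoms
    if symptoms.shape[1] < 2:
        raise ConfigurationError("need at least 2 symptom columns")
    constant = [c for c in symptoms.columns if symptoms[c].nunique() < 2]
    if constant:
        logger.warning("dropping %d constant symptom column(s): %s",
                       len(constant), constant)
        symptoms = symptoms.drop(columns=constant)
    if symptoms.shape[1] < 2:
        raise ConfigurationError("fewer than 2 non-constant symptom columns")

    names = list(symptoms.columns)
    x = symptoms.to_numpy(dtype=np.int8)
    n, p = x.shape
    co, ones = _joint_counts(x)
    iu, ju = np.triu_indices(p, k=1)
    mi = np.empty(iu.size)
    for t in range(iu.size):
        mi[t] = _mi_from_margins(
            co[iu[t], ju[t]], int(ones[iu[t]]), int(ones[ju[t]]), n
        ).item()

    pairs = [tuple(sorted((names[i], names[j]))) for i, j in zip(iu, ju)]

    if config.edge_budget is not None:
        m = config.edge_budget
        if m > iu.size:
            raise ConfigurationError(
                f"edge_budget {m} exceeds {iu.size} available pairs"
            )
        order = sorted(range(iu.size), key=lambda t: (-mi[t], pairs[t]))
        chosen = order[:m]
        edges = [
            AssociationEdge(pairs[t][0], pairs[t][1], float(mi[t]))
            for t in chosen
        ]
    else:
        rng = np.random.default_rng(config.random_seed)
        nperm = config.n_permutations
        edges = []
        for t in range(iu.size):
            kx, ky = int(ones[iu[t]]), int(ones[ju[t]])
            null_n11 = rng.hypergeometric(kx, n - kx, ky, size=nperm)
            null_mi = _mi_from_margins(null_n11, kx, ky, n)
            pval = (1 + np.sum(null_mi >= mi[t] - 1e-12)) / (nperm + 1)
            if pval < config.alpha_perm:
                edges.append(
                    AssociationEdge(
                        pairs[t][0], pairs[t][1], float(mi[t]), float(pval)
                    )
                )
    edges.sort(key=lambda e: (-e.mi, e.pair))
    return AssociationNetwork(nodes=names, edges=edges)


def write_pajek(network: AssociationNetwork, path) -> None:
    """Write the standard Pajek .net dialect: ``*Vertices n``, 1-based
    ``i "label"`` lines, ``*Edges``, ``i j`` lines."""
    if not network.nodes:
        raise ValueError("cannot write a network with no vertices")
    idx = {v: i + 1 for i, v in enumerate(network.nodes)}
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"*Vertices {network.n_nodes}\n")
        for v in network.nodes:
            f.write(f'{idx[v]} "{v}"\n')
        f.write("*Edges\n")
        for e in network.edges:
            f.write(f"{idx[e.symptom_a]} {idx[e.symptom_b]}\n")


class PajekParseError(ValueError):
    pass


def read_pajek(path) -> AssociationNetwork:
    """Read the dialect written by :func:`write_pajek`."""
    with open(path, encoding="utf-8") as f:
        lines = [ln.strip() for ln in f if ln.strip()]
    if not lines or not lines[0].lower().startswith("*vertices"):
        raise PajekParseError(f"{path}: missing *Vertices header")
    try:
        n = int(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise PajekParseError(f"{path}: malformed *Vertices header") from exc
    nodes: list[str] = []
    pos = 1
    while pos < len(lines) and not lines[pos].startswith("*"):
        line = lines[pos]
        i_str, _, rest = line.partition(" ")
        label = rest.strip()
        if label.startswith('"') and label.endswith('"'):
            label = label[1:-1]
        try:
            i = int(i_str)
        except ValueError as exc:
            raise PajekParseError(f"{path}: bad vertex line {line!r}") from exc
        if i != len(nodes) + 1:
            raise PajekParseError(f"{path}: vertex ids must be 1..n in order")
        nodes.append(label if label else str(i))
        pos += 1
    if len(nodes) != n:
        raise PajekParseError(
            f"{path}: header says {n} vertices, found {len(nodes)}"
        )
    edges: list[AssociationEdge] = []
    if pos < len(lines):
        if lines[pos].lower().split()[0] not in ("*edges", "*arcs"):
            raise PajekParseError(f"{path}: expected *Edges, got {lines[pos]!r}")
        for line in lines[pos + 1:]:
            parts = line.split()
            if len(parts) < 2:
                raise PajekParseError(f"{path}: bad edge line {line!r}")
            i, j = int(parts[0]), int(parts[1])
            if not (1 <= i <= n and 1 <= j <= n):
                raise PajekParseError(
                    f"{path}: vertex index out of range in {line!r}"
                )
            edges.append(AssociationEdge(nodes[i - 1], nodes[j - 1], mi=0.0))
    return AssociationNetwork(nodes=nodes, edges=edges)


def write_adjacency_tsv(network: AssociationNetwork, path) -> None:
    """Adjacency matrix as TSV, symptom names as header and first column."""
    network.adjacency_matrix().to_csv(path, sep="\t", index_label="")
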
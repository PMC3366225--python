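"""Degree and k-core analysis of symptom association networks.

The k-core of a graph is the maximal subgraph in which every node has at
least k neighbours inside the subgraph; a node's core value is the largest
k for which it survives. Core values are computed by the standard
minimum-degree peeling algorithm (bucket-based, linear in edges). The
central high-core symptoms are then grouped by a configurable
symptom-to-syndrome mapping to summarize which TCM syndromes the network
core represents.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from . import vocab
from .network import AssociationNetwork

VALID_SYNDROME_LABELS = frozenset(vocab.SYNDROMES) | {
    vocab.UNASSIGNED,
    vocab.PHLEGM_BLOOD_STASIS,
}


def validate_syndrome_map(syndrome_map: dict[str, str]) -> None:
    """Check map values against the seven network syndromes (plus the
    composite phlegm-blood stasis target and 'unassigned')."""
    bad = {s: v for s, v in syndrome_map.items()
           if v not in VALID_SYNDROME_LABELS}
    if bad:
        raise ValueError(f"unknown syndrome labels in map: {bad}")


def node_degrees(network: AssociationNetwork) -> pd.Series:
    """Degree of each node (number of incident edges), in node order."""
    deg = {v: 0 for v in network.nodes}
    for e in network.edges:
        deg[e.symptom_a] += 1
        deg[e.symptom_b] += 1
    return pd.Series(deg, name="degree")


def _adjacency_lists(network: AssociationNetwork) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {v: [] for v in network.nodes}
    for e in network.edges:
        adj[e.symptom_a].append(e.symptom_b)
        adj[e.symptom_b].append(e.symptom_a)
    return adj


def core_numbers(network: AssociationNetwork) -> dict[str, int]:
    """Core value of every node by bucket peeling.

    Nodes are kept in buckets by current degree; repeatedly remove a
    minimum-degree node, assign it the running core value, and decrement its
    remaining neighbours. O(V + E).
    """
    adj = _adjacency_lists(network)
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    if not degree:
        return {}
    max_deg = max(degree.values())
    buckets: list[list[str]] = [[] for _ in range(max_deg + 1)]
    for v in network.nodes:
        buckets[degree[v]].append(v)
    core: dict[str, int] = {}
    removed: set[str] = set()
    k = 0
    for _ in range(len(degree)):
        d = 0
        while True:
            while buckets[d] and buckets[d][-1] in removed:
                buckets[d].pop()
            # stale entries: node may have been re-bucketed at a lower degree
            if buckets[d] and degree[buckets[d][-1]] != d:
                buckets[d].pop()
                continue
            if buckets[d]:
                break
            d += 1
        v = buckets[d].pop()
        removed.add(v)
        k = max(k, d)
        core[v] = k
        for w in adj[v]:
            if w not in removed:
                degree[w] -= 1
                buckets[degree[w]].append(w)
    return core


def kcore_decompose(network: AssociationNetwork) -> pd.DataFrame:
    """Per-node degree and core value table (columns: node, degree, core)."""
    deg = node_degrees(network)
    core = core_numbers(network)
    return pd.DataFrame(
        {
            "node": network.nodes,
            "degree": [int(deg[v]) for v in network.nodes],
            "core": [core[v] for v in network.nodes],
        }
    )


def extract_kcore(network: AssociationNetwork, k: int) -> AssociationNetwork:
    """Induced subgraph on nodes with core value >= k (may be empty)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    core = core_numbers(network)
    return network.subgraph([v for v in network.nodes if core[v] >= k])


def label_core_syndromes(
    cores: pd.DataFrame,
    syndrome_map: dict[str, str] | None = None,
    k: int = 3,
) -> dict[str, list[str]]:
    """Group nodes with core >= k by their mapped syndrome.

    Unmapped nodes fall under 'unassigned'. Returns syndrome -> sorted node
    list, syndromes in canonical order, 'unassigned' last.
    """
    if syndrome_map is None:
        syndrome_map = vocab.DEFAULT_SYNDROME_MAP
    validate_syndrome_map(syndrome_map)
    selected = cores.loc[cores["core"] >= k, "node"].tolist()
    groups: dict[str, list[str]] = {}
    for node in selected:
        groups.setdefault(
            syndrome_map.get(node, vocab.UNASSIGNED), []
        ).append(node)
    order = list(vocab.SYNDROMES) + [vocab.PHLEGM_BLOOD_STASIS, vocab.UNASSIGNED]
    return {
        s: sorted(groups[s]) for s in order if s in groups
    }


def write_core_table(cores: pd.DataFrame, path) -> None:
    cores.to_csv(path, sep="\t", index=False)


def read_core_table(path) -> pd.DataFrame:
    """Read a node/degree/core TSV (the published network-property table
    ships in this schema)."""
    table = pd.read_csv(path, sep="\t")
    missing = {"node", "degree", "core"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def load_reference_core_table() -> pd.DataFrame:
    """The packaged published property table of the 69-symptom network."""
    ref = importlib.resources.files("zhengmine.fixtures").joinpath(
        "table1_network_properties.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_core_table(path)
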
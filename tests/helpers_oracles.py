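"""Independent brute-force oracles used by several test modules.

Each oracle is deliberately naive and shares no code with the package's
implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from zhengmine.network import AssociationEdge, AssociationNetwork


def mi_bits_bruteforce(table_2x2) -> float:
    """Direct four-cell summation of mutual information in bits."""
    n = sum(sum(row) for row in table_2x2)
    mi = 0.0
    for a in range(2):
        for b in range(2):
            pab = table_2x2[a][b] / n
            if pab == 0:
                continue
            pa = sum(table_2x2[a]) / n
            pb = (table_2x2[0][b] + table_2x2[1][b]) / n
            mi += pab * math.log2(pab / (pa * pb))
    return mi


def kcore_by_repeated_deletion(nodes, edge_pairs) -> dict[str, int]:
    """Core numbers via the fixpoint definition: for each k, repeatedly
    delete nodes of internal degree < k until none remain; a node's core is
    the largest k whose surviving subgraph contains it."""
    core = {v: 0 for v in nodes}
    max_k = len(nodes)
    for k in range(1, max_k + 1):
        alive = set(nodes)
        while True:
            degree = {v: 0 for v in alive}
            for a, b in edge_pairs:
                if a in alive and b in alive:
                    degree[a] += 1
                    degree[b] += 1
            doomed = [v for v in alive if degree[v] < k]
            if not doomed:
                break
            alive -= set(doomed)
        if not alive:
            break
        for v in alive:
            core[v] = k
    return core


def random_graph(n: int, p: float, seed: int) -> AssociationNetwork:
    """Erdős–Rényi G(n, p) as an AssociationNetwork."""
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        AssociationEdge(nodes[i], nodes[j], mi=1.0)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return AssociationNetwork(nodes=nodes, edges=edges)


def count_partitions(c: int, r: int) -> int:
    """Enumerate partitions of c labelled items into exactly r nonempty
    groups (restricted-growth strings)."""
    count = 0
    for assignment in itertools.product(range(r), repeat=c):
        if len(set(assignment)) != r:
            continue
        # canonical: first occurrences of group ids appear in order
        seen: list[int] = []
        for g in assignment:
            if g not in seen:
                seen.append(g)
        if seen == sorted(seen):
            count += 1
    return count


def count_contiguous_groupings(c: int, r: int) -> int:
    """Enumerate ways to cut an ordered c-sequence into r contiguous runs."""
    positions = list(range(1, c))
    return sum(1 for _ in itertools.combinations(positions, r - 1))


def best_contiguous_grouping_by_chi2(counts: np.ndarray, r: int):
    """Exhaustive search over contiguous r-groupings of an ordered c x 2
    count table, maximizing the Pearson statistic."""
    c = counts.shape[0]
    best, best_chi2 = None, -1.0
    for cuts in itertools.combinations(range(1, c), r - 1):
        bounds = [0, *cuts, c]
        rows = np.array(
            [counts[bounds[i]:bounds[i + 1]].sum(axis=0) for i in range(r)],
            dtype=float,
        )
        n = rows.sum()
        expected = np.outer(rows.sum(axis=1), rows.sum(axis=0)) / n
        if (expected == 0).any():
            continue
        chi2 = ((rows - expected) ** 2 / expected).sum()
        if chi2 > best_chi2:
            best_chi2 = chi2
            best = [
                tuple(range(bounds[i], bounds[i + 1])) for i in range(r)
            ]
    return best, best_chi2
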
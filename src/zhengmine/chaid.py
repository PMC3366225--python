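"""Chi-squared Automatic Interaction Detection (CHAID) trees.

A from-scratch implementation of Kass's 1980 recursive partitioning scheme
for a categorical response: continuous predictors are discretized into
ordered quantile bins; within each node, each predictor's categories are
merged stepwise (any pair for nominal predictors, adjacent pairs for
ordinal) while the pairwise chi-square test is non-significant; the node
splits on the predictor whose merged grouping has the smallest
Bonferroni-adjusted p-value, subject to parent/child node-size minimums, a
depth limit, and the split significance level. The Bonferroni multiplier
counts the number of ways the observed categories can be reduced to the
final grouping: Stirling numbers of the second kind for nominal scales,
binomial coefficients (contiguous splits) for ordinal ones.

No re-splitting of merged compound categories and no pruning; Pearson's
statistic only. Fitting is deterministic: predictor ties on adjusted
p-value break by raw p, then by predictor name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import comb, factorial
from typing import Any

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

TREE_SCHEMA_VERSION = 1
MISSING_CATEGORY = "(missing)"

NOMINAL = "nominal"
ORDINAL = "ordinal"


class TreeSchemaError(ValueError):
    """Tree JSON does not match the expected schema/version."""


@dataclass(frozen=True)
class ChaidConfig:
    """Stopping and significance settings.

    Defaults mirror the reference analysis: merge/split alpha 0.05,
    parent-node minimum 50, child-node minimum 25, depth 3, at most 10
    quantile bins per continuous predictor.
    """

    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    parent_min: int = 50
    child_min: int = 25
    max_depth: int = 3
    max_bins: int = 10
    predictor_scales: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_merge <= 1 or not 0 <= self.alpha_split <= 1:
            raise ValueError("alpha levels must lie in (0, 1]")
        if self.child_min < 1:
            raise ValueError("child_min must be >= 1")
        if self.parent_min < self.child_min:
            raise ValueError("parent_min must be >= child_min")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_bins < 2:
            raise ValueError("max_bins must be >= 2")
        for name, scale in self.predictor_scales.items():
            if scale not in (NOMINAL, ORDINAL):
                raise ValueError(f"unknown scale {scale!r} for {name!r}")


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    bonferroni_B: int = 1
    p_adjusted: float = 1.0
    c: int = 1
    r: int = 1


def pearson_chi2(table) -> ChiSquareResult:
    """Pearson chi-square of an r x k contingency table of counts.

    Zero-margin rows/columns are dropped with a warning before testing;
    degrees of freedom are (r-1)(k-1) on the retained table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain nonnegative integer counts")
    rows = obs.sum(axis=1) > 0
    cols = obs.sum(axis=0) > 0
    if (~rows).any() or (~cols).any():
        logger.warning(
            "dropping %d zero row(s) and %d zero column(s) before chi-square",
            int((~rows).sum()), int((~cols).sum()),
        )
        obs = obs[rows][:, cols]
    r, k = obs.shape
    if r < 2 or k < 2:
        raise ValueError("need at least 2 nonempty rows and columns")
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (k - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ChiSquareResult(chi2=chi2, df=df, p=p)


def bonferroni_multiplier(c: int, r: int, scale: str) -> int:
    """Number of ways c observed categories reduce to r groups.

    Nominal: partitions of c labelled categories into r nonempty groups —
    the Stirling number of the second kind, by the alternating-sum formula.
    Ordinal: contiguous groupings of an ordered sequence, C(c-1, r-1).
    """
    if not 1 <= r <= c:
        raise ValueError(f"need 1 <= r <= c, got r={r}, c={c}")
    if scale == ORDINAL:
        return comb(c - 1, r - 1)
    if scale == NOMINAL:
        total = sum(
            (-1) ** i * comb(r, i) * (r - i) ** c for i in range(r + 1)
        )
        return total // factorial(r)
    raise ValueError(f"unknown scale {scale!r}")


def bin_continuous(
    values, max_bins: int = 10
) -> tuple[pd.Series, np.ndarray]:
    """Equal-frequency (quantile) binning into at most max_bins ordered bins.

    Duplicate quantile edges are collapsed, so heavily tied data yields
    fewer bins; a constant vector yields a single bin. Missing values are
    excluded from binning and left missing in the returned codes. Returns
    integer bin codes (missing = -1) and the bin edges, from which the same
    binning can be reproduced on new data.
    """
    ser = pd.Series(np.asarray(values, dtype=float))
    finite = ser.dropna()
    if finite.empty:
        raise ValueError("all values missing; cannot bin")
    if finite.nunique() == 1:
        edges = np.array([-np.inf, np.inf])
    else:
        qs = np.linspace(0, 1, max_bins + 1)
        edges = np.unique(finite.quantile(qs).to_numpy())
        edges[0], edges[-1] = -np.inf, np.inf
    codes = pd.cut(ser, bins=edges, labels=False, right=True)
    codes = codes.fillna(-1).astype(int)
    codes[ser.isna()] = -1
    return codes, edges


def apply_bins(values, edges: np.ndarray) -> pd.Series:
    """Map new values onto previously computed bin edges (missing = -1)."""
    ser = pd.Series(np.asarray(values, dtype=float))
    codes = pd.cut(ser, bins=edges, labels=False, right=True)
    codes = codes.fillna(-1).astype(int)
    codes[ser.isna()] = -1
    # values outside the original range clamp into the edge bins
    codes[(ser < edges[0]) & ser.notna()] = 0
    codes[(ser > edges[-1]) & ser.notna()] = len(edges) - 2
    return codes


@dataclass
class MergeResult:
    groups: list[tuple[Any, ...]]
    result: ChiSquareResult
    sizes: list[int] = field(default_factory=list)


def _pair_p_values(
    table: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Pearson p for each candidate group pair's 2 x k subtable, vectorized.

    Zero response columns within a pair reduce the degrees of freedom (as if
    dropped); pairs indistinguishable through the response — an empty group
    or fewer than two nonzero columns — get p = 1.
    """
    obs = np.stack(
        [table[[a for a, _ in pairs]], table[[b for _, b in pairs]]], axis=1
    ).astype(float)  # (P, 2, k)
    rows = obs.sum(axis=2)
    cols = obs.sum(axis=1)
    n = rows.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows[:, :, None] * cols[:, None, :] / n[:, None, None]
        cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    chi2 = cells.sum(axis=(1, 2))
    nonzero_cols = (cols > 0).sum(axis=1)
    df = np.maximum(nonzero_cols - 1, 1)
    p = special.chdtrc(df, chi2)
    degenerate = (rows == 0).any(axis=1) | (nonzero_cols < 2) | (n == 0)
    return np.where(degenerate, 1.0, p)


def merge_categories(
    pred, resp, config: ChaidConfig, scale: str = ORDINAL
) -> MergeResult:
    """Kass's stepwise category merging for one predictor at one node.

    Repeatedly test each eligible pair of category groups (all pairs when
    nominal; adjacent pairs when ordinal, with the missing category floating
    — free to join any group) against the response on its 2 x k subtable;
    merge the least-significantly-different pair while its p exceeds
    alpha_merge. The returned ChiSquareResult carries the full merged-table
    statistic with the Bonferroni multiplier for (c observed, r final).
    """
    if len(pred) != len(resp):
        raise ValueError("predictor and response lengths differ")
    observed, pcodes = np.unique(np.asarray(pred), return_inverse=True)
    classes, ycodes = np.unique(np.asarray(resp), return_inverse=True)
    observed = [o.item() if hasattr(o, "item") else o for o in observed]
    c, k = len(observed), len(classes)
    if c < 2 or k < 2:
        return MergeResult(
            groups=[tuple(observed)],
            result=ChiSquareResult(0.0, 0, 1.0, 1, 1.0, c, 1),
            sizes=[len(pred)],
        )
    counts = np.bincount(pcodes * k + ycodes, minlength=c * k).reshape(c, k)
    groups_idx: list[tuple[int, ...]] = [(i,) for i in range(c)]
    # a missing-value bin (-1) sorts first among the ordinal codes
    has_floating = scale == ORDINAL and observed[0] == -1

    def values(idx_group: tuple[int, ...]) -> tuple[Any, ...]:
        return tuple(observed[i] for i in idx_group)

    while len(groups_idx) > 1:
        table = np.array([counts[list(g)].sum(axis=0) for g in groups_idx])
        groups_vals = [values(g) for g in groups_idx]
        pairs = _candidate_pairs(groups_vals, scale, has_floating)
        if not pairs:
            break
        pvals = _pair_p_values(table, pairs)
        best = int(np.argmax(pvals > pvals.max() - 1e-12))
        if pvals[best] <= config.alpha_merge:
            break
        a, b = pairs[best]
        merged = tuple(sorted(groups_idx[a] + groups_idx[b]))
        groups_idx = [g for i, g in enumerate(groups_idx) if i not in (a, b)]
        groups_idx.append(merged)
        groups_idx.sort()

    r = len(groups_idx)
    groups = [values(g) for g in groups_idx]
    sizes = [int(counts[list(g)].sum()) for g in groups_idx]
    if r < 2:
        return MergeResult(
            groups=groups,
            result=ChiSquareResult(0.0, 0, 1.0, 1, 1.0, c, r),
            sizes=sizes,
        )
    table = np.array([counts[list(g)].sum(axis=0) for g in groups_idx])
    base = pearson_chi2(table)
    b_mult = bonferroni_multiplier(c, r, scale)
    return MergeResult(
        groups=groups,
        result=ChiSquareResult(
            chi2=base.chi2, df=base.df, p=base.p, bonferroni_B=b_mult,
            p_adjusted=min(1.0, b_mult * base.p), c=c, r=r,
        ),
        sizes=sizes,
    )


def _candidate_pairs(
    groups: list[tuple[Any, ...]], scale: str, has_floating: bool
) -> list[tuple[int, int]]:
    k = len(groups)
    if scale == NOMINAL:
        return [(i, j) for i in range(k) for j in range(i + 1, k)]
    floating = [
        i for i in range(k) if has_floating and -1 in groups[i]
    ]
    ordered = [i for i in range(k) if i not in floating]
    pairs = [
        (ordered[t], ordered[t + 1]) for t in range(len(ordered) - 1)
    ]
    for fi in floating:
        pairs.extend(tuple(sorted((fi, oi))) for oi in ordered)
    return sorted(set(pairs))


@dataclass
class ChaidNode:
    node_id: int
    depth: int
    n: int
    class_counts: dict[Any, int]
    split_predictor: str | None = None
    split_result: ChiSquareResult | None = None
    groups: list[tuple[Any, ...]] = field(default_factory=list)
    children: list["ChaidNode"] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def majority_class(self) -> Any:
        # deterministic tie-break: larger count, then smaller class label
        return sorted(
            self.class_counts.items(), key=lambda kv: (-kv[1], str(kv[0]))
        )[0][0]


@dataclass
class ChaidTree:
    root: ChaidNode
    config: ChaidConfig
    classes: list[Any]
    bin_edges: dict[str, list[float]]
    scales: dict[str, str]
    constant_target: bool = False

    def nodes(self) -> list[ChaidNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes())

    @property
    def n_terminal(self) -> int:
        return sum(node.is_terminal for node in self.nodes())

    @property
    def depth(self) -> int:
        return max(node.depth for node in self.nodes())


def _prepare_features(
    features: pd.DataFrame, config: ChaidConfig
) -> tuple[pd.DataFrame, dict[str, list[float]], dict[str, str]]:
    """Discretize continuous columns once, globally; categorical columns
    become nominal with missing as its own category."""
    prepared = {}
    edges: dict[str, list[float]] = {}
    scales: dict[str, str] = {}
    for col in features.columns:
        declared = config.predictor_scales.get(col)
        is_numeric = pd.api.types.is_numeric_dtype(features[col])
        if is_numeric and declared != NOMINAL:
            codes, e = bin_continuous(features[col], config.max_bins)
            prepared[col] = codes
            edges[col] = [float(v) for v in e]
            scales[col] = ORDINAL
        else:
            vals = features[col].astype(object).where(
                features[col].notna(), MISSING_CATEGORY
            )
            prepared[col] = vals.astype(str)
            scales[col] = declared or NOMINAL
    return pd.DataFrame(prepared, index=features.index), edges, scales


def fit_chaid(
    features: pd.DataFrame, target: pd.Series, config: ChaidConfig | None = None
) -> ChaidTree:
    """Grow a CHAID tree for a binary (or categorical) target.

    A node is considered for splitting when it holds at least parent_min
    cases, is above the depth limit and impure; candidate predictors whose
    merged grouping would create a child below child_min are discarded; the
    node splits on the smallest Bonferroni-adjusted p-value if it is at most
    alpha_split. A constant target yields a flagged root-only tree.
    """
    config = config or ChaidConfig()
    if features.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if len(features) != len(target):
        raise ValueError("features and target lengths differ")
    target = target.reset_index(drop=True)
    features = features.reset_index(drop=True)
    classes = sorted(target.unique().tolist())
    prepared, edges, scales = _prepare_features(features, config)
    columns = sorted(prepared.columns)
    arrays = {col: prepared[col].to_numpy() for col in columns}
    y = target.to_numpy()

    constant = len(classes) < 2
    if constant:
        logger.warning("target is constant; returning root-only tree")

    counter = [0]

    def new_node(index: np.ndarray, depth: int) -> ChaidNode:
        node_id = counter[0]
        counter[0] += 1
        sub_t = y[index]
        counts = {cls: int(np.sum(sub_t == cls)) for cls in classes}
        node = ChaidNode(
            node_id=node_id, depth=depth, n=len(index), class_counts=counts
        )
        if (
            constant
            or depth >= config.max_depth
            or len(index) < config.parent_min
            or max(counts.values(), default=0) == sum(counts.values())
        ):
            return node
        best: tuple[tuple[float, float, str], str, MergeResult] | None = None
        for col in columns:
            pred = arrays[col][index]
            merged = merge_categories(pred, sub_t, config, scales[col])
            if merged.result.r < 2:
                continue
            if min(merged.sizes) < config.child_min:
                continue
            key = (merged.result.p_adjusted, merged.result.p, col)
            if best is None or key < best[0]:
                best = (key, col, merged)
        if best is None or best[0][0] > config.alpha_split:
            return node
        _, col, merged = best
        node.split_predictor = col
        node.split_result = merged.result
        node.groups = merged.groups
        pred = arrays[col][index]
        for grp in merged.groups:
            child_index = index[np.isin(pred, list(grp))]
            node.children.append(new_node(child_index, depth + 1))
        return node

    root = new_node(np.arange(len(target)), 0)
    return ChaidTree(
        root=root, config=config, classes=classes, bin_edges=edges,
        scales=scales, constant_target=constant,
    )


def _route(tree: ChaidTree, node: ChaidNode, row: pd.Series) -> ChaidNode:
    while not node.is_terminal:
        col = node.split_predictor
        value = row[col]
        if tree.scales[col] == ORDINAL and col in tree.bin_edges:
            cat = int(
                apply_bins([value], np.asarray(tree.bin_edges[col])).iloc[0]
            )
        else:
            cat = MISSING_CATEGORY if pd.isna(value) else str(value)
        child = None
        for grp, cand in zip(node.groups, node.children):
            if cat in grp:
                child = cand
                break
        if child is None:  # unseen category: follow the largest child
            logger.debug(
                "category %r of %r unseen at node %d; routing to largest child",
                cat, col, node.node_id,
            )
            child = max(node.children, key=lambda ch: ch.n)
        node = child
    return node


def predict(
    tree: ChaidTree, features: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Route cases to leaves; return majority-class calls and per-class
    leaf proportions."""
    needed = {
        node.split_predictor for node in tree.nodes() if node.split_predictor
    }
    missing = needed - set(features.columns)
    if missing:
        raise KeyError(f"missing split predictor column(s): {sorted(missing)}")
    calls, probs = [], []
    for _, row in features.iterrows():
        leaf = _route(tree, tree.root, row)
        total = max(leaf.n, 1)
        calls.append(leaf.majority_class)
        probs.append(
            {cls: leaf.class_counts.get(cls, 0) / total for cls in tree.classes}
        )
    return (
        pd.Series(calls, index=features.index, name="prediction"),
        pd.DataFrame(probs, index=features.index),
    )


# ---------------------------------------------------------------- I/O ----

def _node_to_dict(node: ChaidNode) -> dict:
    d = {
        "node_id": node.node_id,
        "depth": node.depth,
        "n": node.n,
        "class_counts": {str(k): v for k, v in node.class_counts.items()},
        "split_predictor": node.split_predictor,
        "groups": [list(g) for g in node.groups],
        "children": [_node_to_dict(ch) for ch in node.children],
    }
    if node.split_result is not None:
        d["split_result"] = vars(node.split_result)
    return d


def _node_from_dict(d: dict, classes: list) -> ChaidNode:
    by_str = {str(cls): cls for cls in classes}
    res = d.get("split_result")
    return ChaidNode(
        node_id=d["node_id"],
        depth=d["depth"],
        n=d["n"],
        class_counts={by_str[k]: v for k, v in d["class_counts"].items()},
        split_predictor=d["split_predictor"],
        split_result=ChiSquareResult(**res) if res else None,
        groups=[tuple(g) for g in d["groups"]],
        children=[_node_from_dict(ch, classes) for ch in d["children"]],
    )


def export_tree(tree: ChaidTree, path) -> None:
    payload = {
        "schema_version": TREE_SCHEMA_VERSION,
        "config": {
            **{k: v for k, v in vars(tree.config).items()
               if k != "predictor_scales"},
            "predictor_scales": dict(tree.config.predictor_scales),
        },
        "classes": tree.classes,
        "bin_edges": tree.bin_edges,
        "scales": tree.scales,
        "constant_target": tree.constant_target,
        "root": _node_to_dict(tree.root),
    }
    with open(path, "w", encoding="utf-8") as f:
        json.dump(payload, f, indent=1, default=float)


def import_tree(path) -> ChaidTree:
    try:
        with open(path, encoding="utf-8") as f:
            payload = json.load(f)
    except json.JSONDecodeError as exc:
        raise TreeSchemaError(f"{path}: not valid tree JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != TREE_SCHEMA_VERSION:
        raise TreeSchemaError(
            f"{path}: schema version {version!r}, expected {TREE_SCHEMA_VERSION}"
        )
    try:
        config = ChaidConfig(**payload["config"])
        classes = payload["classes"]
        tree = ChaidTree(
            root=_node_from_dict(payload["root"], classes),
            config=config,
            classes=classes,
            bin_edges={k: list(v) for k, v in payload["bin_edges"].items()},
            scales=payload["scales"],
            constant_target=payload.get("constant_target", False),
        )
    except (KeyError, TypeError) as exc:
        raise TreeSchemaError(f"{path}: malformed tree payload: {exc}") from exc
    return tree


def render_tree(tree: ChaidTree) -> str:
    """Human-readable rendering, one indented block per node."""
    lines: list[str] = []

    def walk(node: ChaidNode, label: str) -> None:
        pad = "  " * node.depth
        counts = ", ".join(
            f"{cls}={node.class_counts.get(cls, 0)}" for cls in tree.classes
        )
        lines.append(f"{pad}node {node.node_id} [{label}] n={node.n} ({counts})")
        if node.split_predictor:
            res = node.split_result
            lines.append(
                f"{pad}  split on {node.split_predictor}: chi2={res.chi2:.3f} "
                f"df={res.df} p_adj={res.p_adjusted:.4g} (B={res.bonferroni_B})"
            )
            for grp, child in zip(node.groups, node.children):
                walk(child, f"{node.split_predictor} in {list(grp)}")

    walk(tree.root, "root")
    return "\n".join(lines) + "\n"
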
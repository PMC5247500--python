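"""Consensus trees and accuracy/resolution statistics against known trees.

All comparisons operate on non-trivial unrooted bipartitions encoded as
bitmasks over the sorted leaf-label order, so rooted and unrooted inputs
mix freely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import Tree

__all__ = [
    "majority_rule_consensus",
    "consensus_from_split_counts",
    "rf_distance",
    "resolution",
    "per_node_accuracy",
    "depth_accuracy_correlation",
    "SpearmanResult",
]


def _check_common_leaves(trees: list[Tree]) -> list[str]:
    leafsets = {frozenset(t.labels) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees must share a common leaf set")
    return sorted(trees[0].labels)


def consensus_from_split_counts(
    counts: Counter | dict,
    n_trees: int,
    labels: list[str],
    threshold: float = 0.5,
) -> Tree:
    """Build the consensus tree containing splits with frequency > threshold.

    ``counts`` maps canonical split bitmasks (bit i = sorted label i; the
    side without bit 0) to occurrence counts. For threshold >= 0.5 the
    retained splits are automatically pairwise compatible.
    """
    if threshold < 0.5:
        raise ValueError("majority-rule threshold must be >= 0.5")
    labels = sorted(labels)
    n = len(labels)
    keep = [m for m, c in counts.items() if c > threshold * n_trees]
    # laminar family of clades (none contains leaf 0): build by containment
    keep.sort(key=lambda m: -bin(m).count("1"))
    n_nodes = n + len(keep) + 1
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    parent = [-1] * n_nodes
    blen = [1.0] * n_nodes
    root = n_nodes - 1
    blen[root] = 0.0
    clade_id = {m: n + i for i, m in enumerate(keep)}

    def smallest_superset(m: int, upto: int) -> int:
        best = root
        best_size = n + 1
        for j in range(upto):
            sup = keep[j]
            if sup & m == m and sup != m:
                size = bin(sup).count("1")
                if size < best_size:
                    best_size = size
                    best = clade_id[sup]
        return best

    for i, m in enumerate(keep):
        p = smallest_superset(m, i)
        parent[clade_id[m]] = p
        children[p].append(clade_id[m])
    for i in range(n):
        m = 1 << i
        p = root
        best_size = n + 1
        for j, sup in enumerate(keep):
            if sup & m and bin(sup).count("1") < best_size:
                best_size = bin(sup).count("1")
                p = clade_id[sup]
        parent[i] = p
        children[p].append(i)
    return Tree(children, parent, blen, labels, root)


def majority_rule_consensus(trees: list[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: splits in strictly more than ``threshold``
    of the input trees; polytomies where no split qualifies."""
    if not trees:
        raise ValueError("need at least one tree")
    labels = _check_common_leaves(trees)
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.split_masks(labels))
    return consensus_from_split_counts(counts, len(trees), labels, threshold)


def rf_distance(tree_a: Tree, tree_b: Tree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    labels = _check_common_leaves([tree_a, tree_b])
    if len(labels) < 4:
        raise ValueError("RF distance needs at least 4 leaves")
    return len(tree_a.split_masks(labels) ^ tree_b.split_masks(labels))


def resolution(tree: Tree, n_leaves: int | None = None) -> float:
    """Fraction of the n-3 possible internal splits present in the tree."""
    n = tree.n_leaves if n_leaves is None else n_leaves
    if n < 4:
        raise ValueError("resolution needs at least 4 leaves")
    return len(tree.split_masks()) / (n - 3)


def per_node_accuracy(
    generating_tree: Tree,
    consensus_trees: list[Tree],
) -> pd.DataFrame:
    """Recovery percentage of every internal node of the generating tree.

    A node counts as recovered in a replicate when its unrooted bipartition
    occurs in that replicate's consensus tree. Depth is the edge count from
    the root of the generating tree.
    """
    labels = _check_common_leaves([generating_tree, *consensus_trees])
    n = len(labels)
    full = (1 << n) - 1
    bit = {lab: 1 << i for i, lab in enumerate(labels)}
    anchor = bit[labels[0]]
    rep_splits = [t.split_masks(labels) for t in consensus_trees]
    depths = generating_tree.node_depths()
    rows = []
    for v in range(generating_tree.n_nodes):
        if not generating_tree.children[v] or v == generating_tree.root:
            continue
        clade = generating_tree.leaf_set(v)
        m = 0
        for lab in clade:
            m |= bit[lab]
        if m & anchor:
            m = full ^ m
        if bin(m).count("1") < 2 or bin(full ^ m).count("1") < 2:
            continue  # trivial split (root-adjacent cherry complement etc.)
        hits = sum(m in s for s in rep_splits)
        rows.append(
            {
                "node": v,
                "clade": ",".join(sorted(clade)),
                "clade_size": len(clade),
                "depth": depths[v],
                "accuracy_pct": 100.0 * hits / max(len(rep_splits), 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    defined: bool = True


def depth_accuracy_correlation(table: pd.DataFrame) -> SpearmanResult:
    """Spearman rank correlation of node recovery percentage vs node depth.

    Positive rho means nodes further from the root (closer to the tips) are
    recovered more often. Undefined (flagged) when either variable is
    constant.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 nodes")
    acc = table["accuracy_pct"].to_numpy(float)
    depth = table["depth"].to_numpy(float)
    if np.ptp(acc) == 0 or np.ptp(depth) == 0:
        return SpearmanResult(float("nan"), float("nan"), defined=False)
    rho, p = stats.spearmanr(depth, acc)
    return SpearmanResult(float(rho), float(p), defined=True)
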
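"""Rooted phylogenetic trees, generating-tree construction and bipartition algebra.

Trees are stored in a flat, index-based form: nodes ``0 .. n_leaves-1`` are
leaves (leaf ``i`` carries ``labels[i]``), higher indices are internal nodes.
Every node except the root has a parent and a length for the edge above it.
Internal nodes may have any number of children, so consensus trees with
polytomies use the same class as fully resolved trees.

Newick reading and writing is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "Bipartition",
    "TreeArrays",
    "make_symmetric_tree",
    "make_asymmetric_tree",
    "assign_branch_lengths",
    "enumerate_topologies",
    "random_resolved_tree",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of the leaf set induced by an internal edge.

    ``clade`` is the canonical side: the side *not* containing the
    lexicographically smallest leaf label. ``other`` is its complement.
    """

    clade: frozenset[str]
    other: frozenset[str]

    def __post_init__(self) -> None:
        if not self.clade or not self.other:
            raise ValueError("both sides of a bipartition must be non-empty")
        if self.clade & self.other:
            raise ValueError("bipartition sides overlap")
        small = min(self.clade | self.other)
        if small in self.clade:
            a, b = self.clade, self.other
            object.__setattr__(self, "clade", b)
            object.__setattr__(self, "other", a)

    def __hash__(self) -> int:  # identity is the unordered pair of sides
        return hash((self.clade, self.other))

    def __repr__(self) -> str:
        return "{%s | %s}" % (
            ",".join(sorted(self.clade)),
            ",".join(sorted(self.other)),
        )


@dataclass
class TreeArrays:
    """Flat representation of a *binary rooted* tree for numerical kernels."""

    post: np.ndarray  # postorder node sequence, root last
    left: np.ndarray  # left child per node, -1 at leaves
    right: np.ndarray  # right child per node, -1 at leaves
    parent: np.ndarray  # parent per node, -1 at root
    blen: np.ndarray  # length of the edge above each node, 0.0 at root
    n_leaves: int


class Tree:
    """Rooted tree with branch lengths and uniquely labelled leaves."""

    __slots__ = ("children", "parent", "blen", "labels", "root")

    def __init__(
        self,
        children: list[list[int]],
        parent: list[int],
        blen: list[float],
        labels: list[str],
        root: int,
    ) -> None:
        self.children = children
        self.parent = parent
        self.blen = blen
        self.labels = list(labels)
        self.root = root
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("leaf labels must be unique")
        for b in blen:
            if b < 0:
                raise ValueError("branch lengths must be non-negative")

    # -- basic structure ---------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def copy(self) -> "Tree":
        return Tree(
            [list(c) for c in self.children],
            list(self.parent),
            list(self.blen),
            list(self.labels),
            self.root,
        )

    def postorder(self) -> list[int]:
        """Node indices, children always before their parent, root last."""
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def is_binary(self) -> bool:
        return all(
            len(c) in (0, 2) for i, c in enumerate(self.children)
        )

    def tree_length(self) -> float:
        return float(sum(self.blen[v] for v in range(self.n_nodes) if v != self.root))

    def node_depths(self) -> dict[int, int]:
        """Depth (edge count from the root) of every node."""
        depth = {self.root: 0}
        for v in self.preorder():
            for c in self.children[v]:
                depth[c] = depth[v] + 1
        return depth

    def leaf_set(self, node: int) -> frozenset[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return frozenset(out)

    # -- splits ------------------------------------------------------------
    def split_masks(self, label_order: Sequence[str] | None = None) -> set[int]:
        """Non-trivial unrooted splits as canonical leaf bitmasks.

        Bit ``i`` corresponds to ``label_order[i]`` (default: sorted labels).
        The canonical orientation is the side not containing bit 0 of the
        order, i.e. the lexicographically smallest label.
        """
        order = sorted(self.labels) if label_order is None else list(label_order)
        if set(order) != set(self.labels):
            raise ValueError("label_order must be a permutation of the leaf labels")
        bit = {lab: 1 << i for i, lab in enumerate(order)}
        n = len(order)
        full = (1 << n) - 1
        anchor = bit[order[0]]
        mask = [0] * self.n_nodes
        for v in self.postorder():
            if not self.children[v]:
                mask[v] = bit[self.labels[v]]
            else:
                m = 0
                for c in self.children[v]:
                    m |= mask[c]
                mask[v] = m
        out: set[int] = set()
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            m = mask[v]
            if m & anchor:
                m = full ^ m
            if m.bit_count() >= 2 and (full ^ m).bit_count() >= 2:
                out.add(m)
        return out

    def splits(self) -> frozenset[Bipartition]:
        """Set of non-trivial bipartitions of the unrooted topology."""
        if self.n_leaves < 4:
            return frozenset()
        order = sorted(self.labels)
        all_labels = frozenset(order)
        out = []
        for m in self.split_masks(order):
            clade = frozenset(order[i] for i in range(len(order)) if m >> i & 1)
            out.append(Bipartition(clade, all_labels - clade))
        return frozenset(out)

    def topology_key(self) -> tuple[frozenset[str], frozenset[int]]:
        """Hashable identifier of the unrooted topology (labels + splits)."""
        return frozenset(self.labels), frozenset(self.split_masks())

    # -- re-rooting --------------------------------------------------------
    def rerooted_above(self, node: int) -> "Tree":
        """Return a copy rooted on the edge above ``node``.

        The edge is split in half; an old root of degree two is removed.
        """
        if node == self.root:
            raise ValueError("cannot reroot above the root")
        adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(self.n_nodes)}
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            p = self.parent[v]
            adj[v].append((p, self.blen[v]))
            adj[p].append((v, self.blen[v]))
        # suppress a degree-2 old root
        if len(adj[self.root]) == 2:
            (a, la), (b, lb) = adj[self.root]
            adj[a] = [(x, l) for x, l in adj[a] if x != self.root] + [(b, la + lb)]
            adj[b] = [(x, l) for x, l in adj[b] if x != self.root] + [(a, la + lb)]
            adj[self.root] = []

        old_parent = self.parent[node]
        if not adj[old_parent]:
            # the old degree-2 root was suppressed: the upward neighbour is
            # the merged-edge endpoint on the far side
            child_set = set(self.children[node])
            ups = [x for x, _ in adj[node] if x not in child_set]
            old_parent = ups[0]
        half = next(l for x, l in adj[node] if x == old_parent) / 2.0
        # remove the edge node--old_parent, hang both off a fresh root
        adj[node] = [(x, l) for x, l in adj[node] if x != old_parent]
        adj[old_parent] = [(x, l) for x, l in adj[old_parent] if x != node]

        n_new = self.n_nodes + 1
        children: list[list[int]] = [[] for _ in range(n_new)]
        parent = [-1] * n_new
        blen = [0.0] * n_new
        new_root = n_new - 1
        children[new_root] = [node, old_parent]
        parent[node] = new_root
        parent[old_parent] = new_root
        blen[node] = half
        blen[old_parent] = half
        seen = {new_root, node, old_parent}
        stack = [node, old_parent]
        while stack:
            v = stack.pop()
            for w, l in adj[v]:
                if w in seen:
                    continue
                seen.add(w)
                parent[w] = v
                children[v].append(w)
                blen[w] = l
                stack.append(w)
        tr = Tree(children, parent, blen, self.labels, new_root)
        return tr._compacted()

    def _compacted(self) -> "Tree":
        """Drop unreachable nodes and renumber (leaves keep ids 0..n-1)."""
        reach = set(self.postorder())
        keep = [v for v in range(self.n_nodes) if v in reach]
        # leaves must stay first and in label order
        leaves = [v for v in keep if not self.children[v]]
        if sorted(leaves) != list(range(self.n_leaves)):
            raise ValueError("leaf indexing corrupted")
        internal = [v for v in keep if self.children[v]]
        newid = {v: i for i, v in enumerate(leaves)}
        newid.update({v: self.n_leaves + i for i, v in enumerate(internal)})
        n = len(keep)
        children: list[list[int]] = [[] for _ in range(n)]
        parent = [-1] * n
        blen = [0.0] * n
        for v in keep:
            nv = newid[v]
            blen[nv] = self.blen[v]
            children[nv] = [newid[c] for c in self.children[v]]
            parent[nv] = newid[self.parent[v]] if self.parent[v] in newid and v != self.root else -1
        return Tree(children, parent, blen, self.labels, newid[self.root])

    def canonicalized(self) -> "Tree":
        """Copy with children everywhere sorted by smallest descendant label."""
        out = self.copy()
        key = {}
        for v in out.postorder():
            if not out.children[v]:
                key[v] = out.labels[v]
            else:
                out.children[v].sort(key=lambda c: key[c])
                key[v] = key[out.children[v][0]]
        return out

    # -- array form --------------------------------------------------------
    def as_arrays(self) -> TreeArrays:
        if not self.is_binary():
            raise ValueError("array form requires a fully resolved binary tree")
        n = self.n_nodes
        left = np.full(n, -1, dtype=np.int32)
        right = np.full(n, -1, dtype=np.int32)
        parent = np.array(self.parent, dtype=np.int32)
        blen = np.asarray(self.blen, dtype=np.float64)
        for v in range(n):
            if self.children[v]:
                left[v], right[v] = self.children[v]
        post = np.array(self.postorder(), dtype=np.int32)
        return TreeArrays(post, left, right, parent, blen, self.n_leaves)

    @classmethod
    def from_arrays(
        cls,
        left: np.ndarray,
        right: np.ndarray,
        parent: np.ndarray,
        blen: np.ndarray,
        root: int,
        labels: Sequence[str],
    ) -> "Tree":
        n = len(parent)
        children = [
            [] if left[v] < 0 else [int(left[v]), int(right[v])] for v in range(n)
        ]
        return cls(children, [int(p) for p in parent], [float(b) for b in blen], list(labels), int(root))

    # -- dendropy bridge / newick -----------------------------------------
    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(sorted(self.labels))
        dtree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: dtree.seed_node}
        for v in self.preorder():
            if v != self.root:
                dn = dnodes[self.parent[v]].new_child()
                dn.edge.length = self.blen[v]
                dnodes[v] = dn
            if not self.children[v]:
                dnodes[v].taxon = tns.get_taxon(self.labels[v])
        dtree.is_rooted = True
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        dnodes = list(dtree.preorder_node_iter())
        leaves = [d for d in dnodes if d.is_leaf()]
        labels = [
            (d.taxon.label if d.taxon is not None else d.label) for d in leaves
        ]
        if any(lab is None for lab in labels):
            raise ValueError("every leaf needs a label")
        idx = {id(d): i for i, d in enumerate(leaves)}
        internal = [d for d in dnodes if not d.is_leaf()]
        for j, d in enumerate(internal):
            idx[id(d)] = len(leaves) + j
        n = len(dnodes)
        children: list[list[int]] = [[] for _ in range(n)]
        parent = [-1] * n
        blen = [0.0] * n
        for d in dnodes:
            v = idx[id(d)]
            if d.parent_node is not None:
                p = idx[id(d.parent_node)]
                parent[v] = p
                children[p].append(v)
                blen[v] = float(d.edge.length) if d.edge.length is not None else 0.0
        root = idx[id(dtree.seed_node)]
        tree = cls(children, parent, blen, labels, root)
        # suppress a degree-2 root left behind by unrooted newick readers
        while len(tree.children[tree.root]) == 1:
            child = tree.children[tree.root][0]
            tree.children[tree.root] = tree.children[child]
            for c in tree.children[child]:
                tree.parent[c] = tree.root
            tree.children[child] = []
            tree = tree._compacted()
        return tree

    def to_newick(self, include_lengths: bool = True) -> str:
        tr = self.canonicalized()
        dtree = tr.to_dendropy()
        s = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not include_lengths,
            unquoted_underscores=True,
        )
        return s.strip()

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    def __repr__(self) -> str:
        return f"<Tree n_leaves={self.n_leaves} n_nodes={self.n_nodes}>"


# -- construction ----------------------------------------------------------

def _leaf_labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def make_symmetric_tree(n_leaves: int) -> Tree:
    """Fully balanced rooted binary tree; every leaf at depth log2(n).

    Leaves are labelled ``t1 .. tn`` left to right. All branch lengths 1.0
    (rescale with :func:`assign_branch_lengths`).
    """
    if n_leaves < 4 or n_leaves & (n_leaves - 1):
        raise ValueError("symmetric tree requires 2^k leaves")
    labels = _leaf_labels(n_leaves)
    children: list[list[int]] = [[] for _ in range(2 * n_leaves - 1)]
    parent = [-1] * (2 * n_leaves - 1)
    blen = [1.0] * (2 * n_leaves - 1)
    nxt = [n_leaves]  # next free internal id

    def build(lo: int, hi: int) -> int:
        if hi - lo == 1:
            return lo
        v = nxt[0]
        nxt[0] += 1
        mid = (lo + hi) // 2
        for c in (build(lo, mid), build(mid, hi)):
            children[v].append(c)
            parent[c] = v
        return v

    root = build(0, n_leaves)
    blen[root] = 0.0
    return Tree(children, parent, blen, labels, root)


def make_asymmetric_tree(
    n_leaves: int,
    labels: Sequence[str] | None = None,
    ultrametric: bool = True,
) -> Tree:
    """Fully pectinate (caterpillar) rooted tree.

    The deepest cherry is ``(t1,t2)`` and each successive internal node adds
    one leaf, ending with ``tn`` attached at the root.

    By default the tree is ultrametric with unit node spacing: internal
    edges have length 1 and each terminal branch stretches to the present,
    so the leaf attached at height h carries a branch of length h. Deep
    divergences are therefore separated by short internal edges relative to
    long terminal branches — the configuration that makes pectinate trees
    genuinely hard to reconstruct. ``ultrametric=False`` gives unit lengths
    on every edge instead.
    """
    if n_leaves < 3:
        raise ValueError("asymmetric tree requires at least 3 leaves")
    labels = list(labels) if labels is not None else _leaf_labels(n_leaves)
    if len(labels) != n_leaves:
        raise ValueError("label count must match n_leaves")
    n_nodes = 2 * n_leaves - 1
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    parent = [-1] * n_nodes
    blen = [1.0] * n_nodes
    cur = n_leaves  # cherry (t1, t2)
    children[cur] = [0, 1]
    parent[0] = parent[1] = cur
    for leaf in range(2, n_leaves):
        v = n_leaves + leaf - 1
        children[v] = [cur, leaf]
        parent[cur] = v
        parent[leaf] = v
        cur = v
    blen[cur] = 0.0
    tree = Tree(children, parent, blen, labels, cur)
    if ultrametric:
        depths = tree.node_depths()
        height = max(depths[v] for v in range(n_leaves))
        for v in range(n_leaves):
            tree.blen[v] = float(height - depths[v] + 1)
    return tree


def assign_branch_lengths(
    tree: Tree,
    scheme: str | Sequence[float] = "unit",
    rate_multiplier: float = 1.0,
) -> Tree:
    """Return a copy with every edge length = base length x multiplier.

    ``scheme="unit"`` uses base length 1.0 on every edge; a sequence gives
    per-edge base lengths in node-index order (root entry ignored).
    """
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be positive")
    out = tree.copy()
    n_edges = tree.n_nodes
    if isinstance(scheme, str):
        if scheme != "unit":
            raise ValueError(f"unknown branch length scheme: {scheme!r}")
        base = [1.0] * n_edges
    else:
        base = [float(b) for b in scheme]
        if len(base) != n_edges:
            raise ValueError(
                f"custom branch length list has length {len(base)}, expected {n_edges}"
            )
    for v in range(n_edges):
        out.blen[v] = 0.0 if v == out.root else base[v] * rate_multiplier
    return out


def splits(tree: Tree) -> frozenset[Bipartition]:
    """Module-level alias for :meth:`Tree.splits`."""
    return tree.splits()


def read_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    return tree.to_newick(include_lengths=include_lengths)


# -- topology enumeration and random trees ---------------------------------

def enumerate_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """All distinct unrooted fully resolved topologies on ``labels``.

    Yields rooted binary :class:`Tree` objects whose unrooted topologies are
    pairwise distinct and exhaustive: (2n-5)!! trees for n leaves. Intended
    for exhaustive oracles at small n.
    """
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")

    def insertions(tree: Tree, leaf: int) -> Iterator[Tree]:
        # insert `leaf` on each edge; skip one root edge (same unrooted result)
        root_children = tree.children[tree.root]
        skip = root_children[1] if len(root_children) == 2 else -1
        for v in range(tree.n_nodes):
            if v == tree.root or v == skip or tree.parent[v] == -1:
                continue
            t = tree.copy()
            while len(t.children) < 2 * n - 1:
                t.children.append([])
                t.parent.append(-1)
                t.blen.append(1.0)
            # next unused internal slot
            free = [u for u in range(n, len(t.children)) if not t.children[u] and t.root != u]
            new_int = free[0]
            p = t.parent[v]
            t.children[p] = [new_int if c == v else c for c in t.children[p]]
            t.children[new_int] = [v, leaf]
            t.parent[new_int] = p
            t.parent[v] = new_int
            t.parent[leaf] = new_int
            t.blen[new_int] = 1.0
            t.blen[leaf] = 1.0
            yield t

    n_nodes = 2 * n - 1
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    parent = [-1] * n_nodes
    blen = [1.0] * n_nodes
    children[n] = [0, 1]
    parent[0] = parent[1] = n
    root = n + 1
    children[root] = [n, 2]
    parent[n] = root
    parent[2] = root
    blen[root] = 0.0
    base = Tree(children, parent, blen, labels, root)

    def rec(tree: Tree, next_leaf: int) -> Iterator[Tree]:
        if next_leaf == n:
            yield tree
            return
        for t in insertions(tree, next_leaf):
            yield from rec(t, next_leaf + 1)

    yield from rec(base, 3)


def random_resolved_tree(
    labels: Sequence[str], rng: np.random.Generator, blen: float = 1.0
) -> Tree:
    """Random fully resolved rooted tree by sequential random edge insertion."""
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    n_nodes = 2 * n - 1
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    parent = [-1] * n_nodes
    lens = [blen] * n_nodes
    order = list(rng.permutation(n))
    a, b, c = order[0], order[1], order[2]
    cherry = n
    children[cherry] = [a, b]
    parent[a] = parent[b] = cherry
    root = n + 1
    children[root] = [cherry, c]
    parent[cherry] = root
    parent[c] = root
    lens[root] = 0.0
    attached = [a, b, c, cherry]
    next_int = n + 2
    for leaf in order[3:]:
        v = attached[int(rng.integers(len(attached)))]
        p = parent[v]
        new_int = next_int
        next_int += 1
        children[p] = [new_int if x == v else x for x in children[p]]
        children[new_int] = [v, leaf]
        parent[new_int] = p
        parent[v] = new_int
        parent[leaf] = new_int
        attached.extend([leaf, new_int])
    return Tree(children, parent, lens, labels, root)
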
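"""Shared fixtures: small trees, matrices and brute-force oracles."""

from itertools import product

import numpy as np
import pytest

from morphobench.mk import gamma_categories, mk_transition
from morphobench.simulate import CharacterMatrix
from morphobench.trees import Tree, random_resolved_tree


@pytest.fixture
def quartet_tree() -> Tree:
    return Tree.from_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.05);")


@pytest.fixture
def quartet_matrix() -> CharacterMatrix:
    states = np.array([[0, 1], [1, 1], [0, 2], [1, 3]], dtype=np.int8)
    return CharacterMatrix(["A", "B", "C", "D"], states, np.array([True, False]))


def random_tree(rng: np.random.Generator, n: int, max_blen: float = 1.0) -> Tree:
    labels = [chr(ord("A") + i) for i in range(n)]
    t = random_resolved_tree(labels, rng)
    for v in range(t.n_nodes):
        if v != t.root:
            t.blen[v] = float(rng.uniform(0.01, max_blen))
    return t


def random_matrix(rng: np.random.Generator, taxa: list[str], n_chars: int,
                  k: int = 4, missing: float = 0.0) -> CharacterMatrix:
    states = rng.integers(0, k, (len(taxa), n_chars)).astype(np.int8)
    if missing:
        states[rng.random(states.shape) < missing] = -1
    is_binary = np.array(
        [states[:, j][states[:, j] >= 0].max(initial=0) <= 1
         for j in range(n_chars)]
    )
    return CharacterMatrix(list(taxa), states, is_binary)


def fitch_brute_force(tree: Tree, column: np.ndarray, n_states: int = 4) -> int:
    """Minimum changes by exhaustive enumeration of internal assignments."""
    arr = tree.as_arrays()
    internals = [int(v) for v in arr.post if arr.left[v] >= 0]
    edges = [(int(arr.parent[v]), v) for v in range(tree.n_nodes)
             if v != int(arr.post[-1])]
    best = np.inf
    for assign in product(range(n_states), repeat=len(internals)):
        state = {v: a for v, a in zip(internals, assign)}
        for leaf in range(tree.n_leaves):
            state[leaf] = int(column[leaf])
        changes = 0
        ok = True
        for p, c in edges:
            sc = state[c]
            if sc < 0:  # missing: choose the parent's state (free)
                continue
            if state[p] != sc:
                changes += 1
        if ok:
            best = min(best, changes)
    return int(best)


def mk_loglik_brute_force(matrix: CharacterMatrix, tree: Tree, alpha: float,
                          n_cat: int = 4, mkv: bool = False) -> float:
    """Likelihood by summation over all internal state assignments."""
    from morphobench.mk import compact_states, state_counts

    kc = state_counts(matrix)
    cst = compact_states(matrix.rows_for(tree.labels))
    rates = gamma_categories(alpha, n_cat)
    arr = tree.as_arrays()
    post = [int(v) for v in arr.post]
    root = post[-1]
    internals = [v for v in post if arr.left[v] >= 0]
    total = 0.0
    for c in range(matrix.n_characters):
        k = int(kc[c])
        lc = 0.0
        for rt in rates:
            P = {v: mk_transition(float(arr.blen[v]), k, float(rt))
                 for v in post if v != root}
            s = 0.0
            for assign in product(range(k), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                for leaf in range(tree.n_leaves):
                    amap[leaf] = int(cst[leaf, c])
                p = 1.0 / k
                for v in post:
                    if v == root:
                        continue
                    sc = amap[v]
                    if sc < 0:  # missing leaf: marginalise
                        p *= 1.0
                    else:
                        p *= P[v][amap[int(arr.parent[v])], sc]
                s += p
            lc += s / n_cat
        if mkv:
            pconst = 0.0
            for j in range(k):
                for rt in rates:
                    P = {v: mk_transition(float(arr.blen[v]), k, float(rt))
                         for v in post if v != root}
                    for assign in product(range(k), repeat=len(internals)):
                        amap = dict(zip(internals, assign))
                        p = 1.0 / k
                        for v in post:
                            if v == root:
                                continue
                            parent_state = amap[int(arr.parent[v])]
                            child_state = amap[v] if v >= tree.n_leaves else j
                            p *= P[v][parent_state, child_state]
                        pconst += p / n_cat
            lc /= 1.0 - pconst
        total += np.log(lc)
    return float(total)
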
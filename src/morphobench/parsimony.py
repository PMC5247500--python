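"""Equal-weights and implied-weights parsimony scoring and heuristic search.

Equal-weights (EW) parsimony scores a tree by the total number of Fitch
steps. Implied weighting (IW, Goloboff) instead maximises the total fit
``F = sum_i k / (k + e_i)`` where ``e_i = s_i - m_i`` is the number of extra
(homoplastic) steps of character ``i`` and ``k`` the concavity constant, so
characters that fit the tree poorly are progressively down-weighted.

The search is a desk-scale surrogate for a full parsimony program: random
addition-sequence starting trees followed by greedy NNI (or SPR)
hill-climbing, pooled over several starts; every topology tying the best
score found is retained for consensus building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .homoplasy import min_steps, tips_mask_for
from .simulate import CharacterMatrix
from .trees import Tree

__all__ = ["ParsimonyConfig", "TreeSearchResult", "ew_score", "iw_score",
           "parsimony_search"]


@dataclass(frozen=True)
class ParsimonyConfig:
    weighting: str = "equal"  # "equal" | "implied"
    k: float = 2.0  # implied-weighting concavity constant
    n_random_starts: int = 10
    move_set: str = "NNI"  # "NNI" | "SPR"
    max_rounds: int = 100
    max_trees: int = 500  # cap on retained tied topologies
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weighting not in ("equal", "implied"):
            raise ValueError("weighting must be 'equal' or 'implied'")
        if self.k <= 0:
            raise ValueError("concavity constant k must be positive")
        if self.n_random_starts < 1:
            raise ValueError("need at least one random start")
        if self.move_set not in ("NNI", "SPR"):
            raise ValueError("move_set must be 'NNI' or 'SPR'")


@dataclass
class TreeSearchResult:
    best_score: float  # EW: total steps (minimised); IW: total fit (maximised)
    best_trees: list[Tree] = field(default_factory=list)
    n_evaluated: int = 0


def _score_arrays(matrix: CharacterMatrix, tree: Tree):
    arr = tree.as_arrays()
    mask = tips_mask_for(matrix, tree)
    steps = np.empty(matrix.n_characters, dtype=np.int64)
    _kernels.fitch_counts(
        arr.post, len(arr.post), arr.left, arr.right, mask, arr.n_leaves, steps
    )
    return steps


def ew_score(matrix: CharacterMatrix, tree: Tree) -> int:
    """Total Fitch steps of the matrix on the tree."""
    return int(_score_arrays(matrix, tree).sum())


def iw_score(matrix: CharacterMatrix, tree: Tree, k: float = 2.0) -> float:
    """Goloboff implied-weights fit F = sum k/(k + e_i); larger is better."""
    if k <= 0:
        raise ValueError("concavity constant k must be positive")
    steps = _score_arrays(matrix, tree)
    extra = np.maximum(steps - min_steps(matrix), 0)
    return float((k / (k + extra)).sum())


def parsimony_search(
    matrix: CharacterMatrix,
    config: ParsimonyConfig = ParsimonyConfig(),
    seed: int | None = None,
) -> TreeSearchResult:
    """Heuristic parsimony tree search.

    Each random start builds a greedy random-addition-sequence tree and
    hill-climbs over the configured move set, accepting strictly better
    rearrangements until a local optimum. Local optima are pooled across
    starts; ``best_trees`` holds every distinct topology attaining the best
    score found (EW ties exact; IW ties within 1e-9).
    """
    if matrix.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    labels = list(matrix.taxa)
    n = len(labels)
    mask = np.where(
        matrix.states >= 0, np.left_shift(1, np.maximum(matrix.states, 0)), 15
    ).astype(np.uint8)
    ms = min_steps(matrix)
    mode = 0 if config.weighting == "equal" else 1
    climb = (
        _kernels.nni_hill_climb if config.move_set == "NNI" else _kernels.spr_hill_climb
    )

    minimised_best = np.inf
    pool: dict = {}
    n_eval = 0
    for _ in range(config.n_random_starts):
        order = rng.permutation(n).astype(np.int64)
        rand_seq = rng.random(64)
        left = np.empty(2 * n - 1, np.int32)
        right = np.empty(2 * n - 1, np.int32)
        parent = np.empty(2 * n - 1, np.int32)
        root, start_score, e1 = _kernels.stepwise_addition(
            order, mask, ms, mode, config.k, left, right, parent, rand_seq
        )
        score, e2 = climb(
            left, right, parent, root, mask, ms, mode, config.k, config.max_rounds
        )
        n_eval += int(e1) + int(e2)
        if score > start_score + 1e-9:  # pragma: no cover - monotonicity guard
            raise AssertionError("hill climb worsened its starting tree")
        blen = np.ones(2 * n - 1)
        tree = Tree.from_arrays(left, right, parent, blen, int(root), labels)
        key = tree.topology_key()
        if score < minimised_best - 1e-9:
            minimised_best = score
            pool = {key: tree}
        elif score <= minimised_best + 1e-9 and key not in pool:
            if len(pool) < config.max_trees:
                pool[key] = tree

    if mode == 0:
        best_score: float = float(int(round(minimised_best)))
    else:
        # kernel minimises sum e/(e+k); report the fit F = N - that
        best_score = float(matrix.n_characters - minimised_best)
    return TreeSearchResult(best_score, list(pool.values()), n_eval)
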
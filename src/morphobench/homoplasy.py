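"""Parsimony step counts, consistency index and CI-matched rejection sampling.

The consistency index (CI) of a matrix on a tree is the ratio of the minimum
conceivable number of state changes (sum over characters of observed states
minus one) to the number of changes actually required on the tree (Fitch
steps). Matrices are admitted to the study by rejection sampling until the
among-matrix CI distribution matches a target histogram over [0.26, 1.0],
emulating the spread of homoplasy seen in empirical morphological datasets.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .simulate import CharacterMatrix, draw_replicate_params, simulate_matrix
from .trees import Tree

__all__ = [
    "CharacterFitRecord",
    "HomoplasyTarget",
    "fitch_steps",
    "character_fits",
    "consistency_index",
    "default_homoplasy_target",
    "bin_match_sampler",
    "ci_matrix_generator",
]

CI_MIN = 0.26
CI_MAX = 1.0


def tips_mask_for(matrix: CharacterMatrix, tree: Tree) -> np.ndarray:
    """uint8 state bitmasks aligned to the tree's leaf order (15 = missing)."""
    states = matrix.rows_for(tree.labels)
    mask = np.where(states >= 0, np.left_shift(1, np.maximum(states, 0)), 15)
    return mask.astype(np.uint8)


def min_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Minimum conceivable steps per character: observed states - 1."""
    return matrix.observed_state_counts().astype(np.int64) - 1


def _steps_on_tree(matrix: CharacterMatrix, tree: Tree) -> np.ndarray:
    arr = tree.as_arrays()
    mask = tips_mask_for(matrix, tree)
    steps = np.empty(matrix.n_characters, dtype=np.int64)
    _kernels.fitch_counts(
        arr.post, len(arr.post), arr.left, arr.right, mask, arr.n_leaves, steps
    )
    return steps


def fitch_steps(
    character_column: Mapping[str, int] | Sequence[int] | np.ndarray,
    tree: Tree,
) -> int:
    """Minimum number of changes for one unordered character on ``tree``.

    ``character_column`` maps leaf labels to states, or gives states in
    ``tree.labels`` order. Missing data is encoded as -1.
    """
    if isinstance(character_column, Mapping):
        missing = set(tree.labels) - set(character_column)
        if missing:
            raise KeyError(f"characters missing for leaves: {sorted(missing)}")
        col = np.array([character_column[lab] for lab in tree.labels], dtype=np.int8)
    else:
        col = np.asarray(character_column, dtype=np.int8)
        if col.shape != (tree.n_leaves,):
            raise ValueError("column length must equal the number of leaves")
    is_binary = np.array([col[col >= 0].max(initial=0) <= 1])
    m = CharacterMatrix(list(tree.labels), col[:, None], is_binary)
    return int(_steps_on_tree(m, tree)[0])


@dataclass(frozen=True)
class CharacterFitRecord:
    """Per-character fit of a matrix on a reference tree."""

    steps: np.ndarray  # s_i: Fitch steps on the tree
    min_steps: np.ndarray  # m_i: observed states - 1

    @property
    def extra_steps(self) -> np.ndarray:
        return self.steps - self.min_steps


def character_fits(matrix: CharacterMatrix, tree: Tree) -> CharacterFitRecord:
    rec = CharacterFitRecord(_steps_on_tree(matrix, tree), min_steps(matrix))
    if np.any(rec.extra_steps < 0):  # pragma: no cover - internal consistency
        raise AssertionError("Fitch steps fell below the conceivable minimum")
    return rec


def consistency_index(matrix: CharacterMatrix, tree: Tree) -> float:
    """CI = sum(m_i) / sum(s_i) over characters requiring at least one step.

    Invariant characters (zero steps on the tree) contribute to neither sum.
    """
    rec = character_fits(matrix, tree)
    var = rec.steps > 0
    total_steps = int(rec.steps[var].sum())
    if total_steps == 0:
        raise ValueError("CI undefined: every character is invariant on the tree")
    return float(rec.min_steps[var].sum() / total_steps)


@dataclass(frozen=True)
class HomoplasyTarget:
    """Target CI histogram for the rejection sampler.

    ``bin_edges`` run from 0.26 to 1.0; bins are half-open [lo, hi) except
    the final bin, which is closed at 1.0.
    """

    bin_edges: np.ndarray
    target_proportions: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        props = np.asarray(self.target_proportions, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if abs(edges[0] - CI_MIN) > 1e-9 or abs(edges[-1] - CI_MAX) > 1e-9:
            raise ValueError(f"bin_edges must span [{CI_MIN}, {CI_MAX}]")
        if len(props) != len(edges) - 1:
            raise ValueError("need one proportion per bin")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "target_proportions", props)

    @property
    def n_bins(self) -> int:
        return len(self.target_proportions)

    def bin_of(self, ci: float) -> int:
        """Bin index for a CI value, or -1 if outside [0.26, 1.0]."""
        if ci < self.bin_edges[0] or ci > self.bin_edges[-1]:
            return -1
        j = int(np.searchsorted(self.bin_edges, ci, side="right") - 1)
        return min(j, self.n_bins - 1)

    def quotas(self, n_total: int) -> np.ndarray:
        """Per-bin acceptance quotas by the largest-remainder method."""
        raw = self.target_proportions * n_total
        base = np.floor(raw).astype(int)
        short = n_total - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
        return base


def default_homoplasy_target() -> HomoplasyTarget:
    """Stand-in target: triangular CI density peaking near 0.6 on [0.26, 1.0].

    The bins are 0.05 wide on the usual grid (first bin [0.26, 0.30), last
    bin [0.95, 1.0]). Users with an empirical CI table should construct a
    :class:`HomoplasyTarget` from it instead.
    """
    edges = np.concatenate([[CI_MIN], np.arange(0.30, 1.0, 0.05), [CI_MAX]])
    peak = 0.6

    def density(x: np.ndarray) -> np.ndarray:
        up = (x - CI_MIN) / (peak - CI_MIN)
        down = (CI_MAX - x) / (CI_MAX - peak)
        return np.where(x <= peak, up, down)

    mids = (edges[:-1] + edges[1:]) / 2
    mass = density(mids) * np.diff(edges)
    return HomoplasyTarget(edges, mass / mass.sum())


def mp_consistency_index(matrix: CharacterMatrix, seed: int = 0) -> float:
    """CI on a most-parsimonious tree found by a quick heuristic search.

    Empirical CI values (the calibration target of the rejection sampler)
    are conventionally computed on the most-parsimonious tree of the matrix
    itself, so simulated matrices must be scored the same way for their CI
    distribution to be comparable. Uses a single random-addition start with
    NNI refinement — a close, slightly conservative proxy for the exact MP
    score.
    """
    from . import _kernels  # local alias keeps the hot path obvious

    n = matrix.n_taxa
    mask = np.where(
        matrix.states >= 0, np.left_shift(1, np.maximum(matrix.states, 0)), 15
    ).astype(np.uint8)
    ms = min_steps(matrix)
    rng = np.random.default_rng(seed)
    left = np.empty(2 * n - 1, np.int32)
    right = np.empty(2 * n - 1, np.int32)
    parent = np.empty(2 * n - 1, np.int32)
    order = rng.permutation(n).astype(np.int64)
    # the addition sequence only seeds the climb: guiding it on a column
    # subsample keeps wide matrices cheap without changing the CI definition
    if matrix.n_characters > 256:
        cols = np.sort(rng.choice(matrix.n_characters, 256, replace=False))
        guide_mask = np.ascontiguousarray(mask[:, cols])
        guide_ms = np.ascontiguousarray(ms[cols])
    else:
        guide_mask, guide_ms = mask, ms
    root, _, _ = _kernels.stepwise_addition(
        order, guide_mask, guide_ms, 0, 2.0, left, right, parent, rng.random(64)
    )
    _kernels.nni_hill_climb(left, right, parent, root, mask, ms, 0, 2.0, 100)
    post = np.empty(2 * n - 1, np.int32)
    m = _kernels.postorder_fill(left, right, root, post)
    steps = np.empty(matrix.n_characters, np.int64)
    _kernels.fitch_counts(post, m, left, right, mask, n, steps)
    var = steps > 0
    total = int(steps[var].sum())
    if total == 0:
        raise ValueError("CI undefined: every character is invariant")
    return float(ms[var].sum() / total)


def ci_matrix_generator(
    tree: Tree,
    n_characters: int = 100,
    binary_fraction: float = 0.55,
    ci_tree: str = "generating",
) -> Callable[[int], tuple[CharacterMatrix, float]]:
    """Replicate factory: seed -> (matrix, CI).

    Each call draws fresh replicate parameters (gamma shape and substitution
    rate ~ Exponential(mean 1)) and simulates a matrix on ``tree``. The CI
    handed to the rejection sampler is computed on the generating tree
    (cheap and deterministic) or, with ``ci_tree="mp"``, on the matrix's own
    heuristically found most-parsimonious tree — the way empirical CI values
    are reported.
    """
    if ci_tree not in ("mp", "generating"):
        raise ValueError("ci_tree must be 'mp' or 'generating'")

    def generate(seed: int) -> tuple[CharacterMatrix, float]:
        params = draw_replicate_params(
            seed, n_characters=n_characters, binary_fraction=binary_fraction
        )
        matrix = simulate_matrix(tree, params, seed=seed)
        try:
            if ci_tree == "mp":
                ci = mp_consistency_index(matrix, seed=seed)
            else:
                ci = consistency_index(matrix, tree)
        except ValueError:
            ci = float("nan")  # all-invariant draw: never accepted
        return matrix, ci

    return generate


def bin_match_sampler(
    generator: Callable[[int], tuple[CharacterMatrix, float]],
    target: HomoplasyTarget,
    n_total: int,
    seed: int,
    max_attempts: int | None = None,
    reallocate_after: int | None = None,
    return_log: bool = False,
):
    """Accept matrices until every CI bin quota is filled.

    Draws ``generator(attempt_seed)`` repeatedly; a draw is accepted when its
    CI falls inside [0.26, 1.0] in a bin whose quota is not yet filled. The
    accepted CI histogram equals ``target.quotas(n_total)`` exactly.

    Some (target, generator) pairs leave a bin quota practically unreachable
    (e.g. wide matrices skip from CI ~0.85 straight to 1.0). With
    ``reallocate_after`` set, once that many draws have been spent any still
    unfilled quota becomes a wildcard: further admissible draws are accepted
    regardless of bin, and the reallocation is visible in the log. By
    default the sampler is strict and raises RuntimeError with the per-bin
    shortfall after ``max_attempts`` draws.

    Returns the list of accepted matrices (with a per-attempt log DataFrame
    when ``return_log``).
    """
    if max_attempts is None:
        max_attempts = max(500 * n_total, 20_000)
    rng = np.random.default_rng(seed)
    quota = target.quotas(n_total)
    filled = np.zeros_like(quota)
    accepted: list[CharacterMatrix] = []
    accepted_ci: list[float] = []
    log: list[dict] = []
    attempts = 0
    while filled.sum() < n_total:
        if attempts >= max_attempts:
            short = {
                f"[{target.bin_edges[i]:.2f},{target.bin_edges[i + 1]:.2f})":
                int(quota[i] - filled[i])
                for i in range(target.n_bins)
                if filled[i] < quota[i]
            }
            raise RuntimeError(
                f"bin-matched sampling stalled after {attempts} attempts; "
                f"unfilled bins: {short}"
            )
        attempt_seed = int(rng.integers(2**31))
        matrix, ci = generator(attempt_seed)
        attempts += 1
        b = -1 if np.isnan(ci) else target.bin_of(ci)
        wildcard = reallocate_after is not None and attempts > reallocate_after
        ok = b >= 0 and (filled[b] < quota[b] or wildcard)
        if ok:
            filled[b if filled[b] < quota[b] else int(np.argmax(quota - filled))] += 1
            accepted.append(matrix)
            accepted_ci.append(ci)
        log.append(
            {
                "attempt": attempts,
                "seed": attempt_seed,
                "ci": ci,
                "bin": b,
                "accepted": bool(ok),
            }
        )
    for m, ci in zip(accepted, accepted_ci):
        m.ci = ci  # annotate for downstream logging
    if return_log:
        return accepted, pd.DataFrame(log)
    return accepted
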
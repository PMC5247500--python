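"""Synthetic morphological matrices evolved under HKY+Gamma on a known tree.

Characters are first simulated as nucleotides under the HKY substitution
model with continuous gamma rate variation among characters, then recoded
into discrete "morphological" states: a fixed fraction of columns is
collapsed to purine/pyrimidine (R/Y) binary characters, the rest map
A,C,G,T -> 0,1,2,3 as unordered multistate characters. Each replicate draws
its own gamma shape and overall substitution rate from Exponential(mean 1)
distributions, which produces matrices spanning a wide range of homoplasy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .trees import Tree

__all__ = [
    "SimulationParams",
    "CharacterMatrix",
    "draw_replicate_params",
    "hky_rate_matrix",
    "hky_transition_matrix",
    "simulate_nucleotides",
    "recode_characters",
    "simulate_matrix",
]

NUCLEOTIDES = "ACGT"
_PYRIMIDINE = (1, 3)  # C, T -> binary state 1; A, G (purines) -> 0


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationParams:
    """All generating-model knobs for one replicate matrix.

    alpha
        Gamma shape for among-character rate variation; the rate parameter is
        set equal to the shape so per-character rates have mean 1.
    mu
        Replicate-level substitution rate; multiplies every branch length.
    kappa
        HKY transition/transversion ratio.
    pi
        Stationary nucleotide frequencies in A,C,G,T order.
    """

    alpha: float
    mu: float
    kappa: float = 2.0
    pi: tuple[float, float, float, float] = (0.2, 0.2, 0.3, 0.3)
    n_characters: int = 100
    binary_fraction: float = 0.55
    seed: int | None = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 4 positive frequencies summing to 1")
        if self.kappa <= 0 or self.alpha <= 0 or self.mu <= 0:
            raise ValueError("kappa, alpha and mu must be positive")
        if not 0.0 <= self.binary_fraction <= 1.0:
            raise ValueError("binary_fraction must lie in [0, 1]")
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")

    def to_yaml(self) -> str:
        d = {
            "alpha": float(self.alpha),
            "mu": float(self.mu),
            "kappa": float(self.kappa),
            "pi": [float(p) for p in self.pi],
            "n_characters": int(self.n_characters),
            "binary_fraction": float(self.binary_fraction),
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationParams":
        d = yaml.safe_load(text)
        d["pi"] = tuple(d["pi"])
        return cls(**d)


class CharacterMatrix:
    """Taxa x characters table of small non-negative integer states.

    Binary columns hold states {0,1}; multistate columns hold {0,1,2,3}.
    ``-1`` encodes missing data (never produced by the simulator, accepted
    when reading user matrices).
    """

    def __init__(
        self,
        taxa: list[str],
        states: np.ndarray,
        is_binary: np.ndarray,
        nucleotides: np.ndarray | None = None,
    ) -> None:
        states = np.asarray(states, dtype=np.int8)
        is_binary = np.asarray(is_binary, dtype=bool)
        if states.ndim != 2 or states.shape[0] != len(taxa):
            raise ValueError("states must be (n_taxa, n_characters)")
        if is_binary.shape != (states.shape[1],):
            raise ValueError("is_binary must have one flag per character")
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon labels must be unique")
        obs = states[:, is_binary]
        if obs.size and obs.max(initial=0) > 1:
            raise ValueError("binary characters must only hold states 0/1")
        if states.max(initial=0) > 3 or states.min(initial=0) < -1:
            raise ValueError("states must lie in {0..3} (-1 for missing)")
        self.taxa = list(taxa)
        self.states = states
        self.is_binary = is_binary
        self.nucleotides = nucleotides

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    @property
    def char_type(self) -> np.ndarray:
        return np.where(self.is_binary, "binary", "multistate")

    def observed_state_counts(self) -> np.ndarray:
        """Number of distinct observed states per character (missing ignored)."""
        out = np.empty(self.n_characters, dtype=np.int64)
        for j in range(self.n_characters):
            col = self.states[:, j]
            out[j] = len(np.unique(col[col >= 0]))
        return out

    def rows_for(self, labels: list[str]) -> np.ndarray:
        """States reordered to match an external taxon order (e.g. tree leaves)."""
        index = {t: i for i, t in enumerate(self.taxa)}
        try:
            rows = [index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"taxon {exc} not present in matrix") from exc
        return self.states[rows]

    def __repr__(self) -> str:
        nb = int(self.is_binary.sum())
        return (
            f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} chars "
            f"({nb} binary, {self.n_characters - nb} multistate)>"
        )


def draw_replicate_params(
    seed: int | np.random.Generator,
    n_characters: int = 100,
    binary_fraction: float = 0.55,
) -> SimulationParams:
    """Draw one replicate's generating parameters.

    The gamma shape (== rate) and the replicate substitution rate are i.i.d.
    Exponential with mean 1; kappa and pi are fixed study constants.
    """
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    rng = _as_rng(seed)
    alpha = float(rng.exponential(1.0))
    mu = float(rng.exponential(1.0))
    return SimulationParams(
        alpha=alpha,
        mu=mu,
        n_characters=n_characters,
        binary_fraction=binary_fraction,
        seed=stored_seed,
    )


def hky_rate_matrix(kappa: float = 2.0, pi=(0.2, 0.2, 0.3, 0.3)) -> np.ndarray:
    """HKY instantaneous rate matrix, normalised to mean rate 1 at stationarity."""
    pi = np.asarray(pi, dtype=float)
    Q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = {i, j} in ({0, 2}, {1, 3})  # A<->G, C<->T
            Q[i, j] = pi[j] * (kappa if transition else 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def _hky_eigen(kappa: float, pi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the HKY generator via pi^(1/2) symmetrisation."""
    pi = np.asarray(pi, dtype=float)
    Q = hky_rate_matrix(kappa, pi)
    d = np.sqrt(pi)
    S = (Q * d[:, None]) / d[None, :]
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    A = V / d[:, None]  # rows scaled by pi^(-1/2)
    B = V.T * d[None, :]
    return w, A, B


def hky_transition_matrix(
    t: float,
    rate: float = 1.0,
    kappa: float = 2.0,
    pi=(0.2, 0.2, 0.3, 0.3),
) -> np.ndarray:
    """Transition probabilities P(t * rate) under HKY. Rows sum to 1."""
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    w, A, B = _hky_eigen(kappa, pi)
    P = (A * np.exp(w * t * rate)) @ B
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def simulate_nucleotides(
    tree: Tree,
    params: SimulationParams,
    n_characters: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Evolve nucleotide characters down the tree under HKY+Gamma(continuous).

    Each character draws a rate r ~ Gamma(shape=alpha, rate=alpha); the edge
    transition matrix on an edge of length b is P(b * mu * r). Returns an
    ``(n_leaves, n_characters)`` int8 array in the order of ``tree.labels``.
    """
    n_chars = params.n_characters if n_characters is None else n_characters
    rng = _as_rng(seed if seed is not None else params.seed)
    pi = np.asarray(params.pi, dtype=float)
    w, A, B = _hky_eigen(params.kappa, pi)
    rates = rng.gamma(shape=params.alpha, scale=1.0 / params.alpha, size=n_chars)
    state = np.empty((tree.n_nodes, n_chars), dtype=np.int8)
    state[tree.root] = rng.choice(4, size=n_chars, p=pi)
    for v in tree.preorder():
        for c in tree.children[v]:
            tau = tree.blen[c] * params.mu * rates  # per-character durations
            expw = np.exp(np.outer(tau, w))  # (n_chars, 4)
            rows = A[state[v]]  # (n_chars, 4)
            probs = (rows * expw) @ B
            np.clip(probs, 0.0, None, out=probs)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n_chars)
            state[c] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return state[: tree.n_leaves]


def recode_characters(
    nucleotides: np.ndarray,
    binary_fraction: float = 0.55,
    seed: int | np.random.Generator | None = None,
    taxa: list[str] | None = None,
) -> CharacterMatrix:
    """Recode nucleotide columns into binary (R/Y) and multistate characters.

    Exactly round(binary_fraction * N) columns (half-up) become binary:
    purines (A,G) -> 0, pyrimidines (C,T) -> 1. The remaining columns map
    A,C,G,T -> 0,1,2,3. Which columns become binary is a uniform random
    choice given the seed.
    """
    nucleotides = np.asarray(nucleotides, dtype=np.int8)
    n_taxa, n_chars = nucleotides.shape
    rng = _as_rng(seed)
    n_binary = int(np.floor(binary_fraction * n_chars + 0.5))
    cols = rng.permutation(n_chars)[:n_binary]
    is_binary = np.zeros(n_chars, dtype=bool)
    is_binary[cols] = True
    states = nucleotides.copy()
    ry = np.isin(nucleotides, _PYRIMIDINE).astype(np.int8)
    states[:, is_binary] = ry[:, is_binary]
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n_taxa)]
    return CharacterMatrix(taxa, states, is_binary, nucleotides=nucleotides)


def simulate_matrix(
    tree: Tree,
    params: SimulationParams,
    seed: int | None = None,
) -> CharacterMatrix:
    """Simulate one replicate matrix on ``tree`` (nucleotides + recoding).

    Fully deterministic given ``(tree, params, seed)``; when ``seed`` is None
    the seed stored in ``params`` is used.
    """
    base = seed if seed is not None else params.seed
    ss = np.random.SeedSequence(base)
    sim_rng = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(1,)))
    recode_rng = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(2,)))
    del ss
    nucs = simulate_nucleotides(tree, params, seed=sim_rng)
    return recode_characters(
        nucs, params.binary_fraction, seed=recode_rng, taxa=list(tree.labels)
    )
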
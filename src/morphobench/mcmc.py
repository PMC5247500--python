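"""Bayesian Mk+Gamma tree inference by Metropolis-Hastings MCMC.

The sampler targets the posterior over (topology, branch lengths, gamma
shape) with independent Exponential branch-length priors, an Exponential
prior on the gamma shape (discretised onto a fixed grid) and a uniform
prior over topologies. Proposals mix NNI and fixed-length SPR topology
moves with multiplier moves on branch lengths and a random walk on the
shape grid. Optional Metropolis coupling runs additional heated chains and
proposes state swaps at fixed intervals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .metrics import consensus_from_split_counts
from .mk import compact_states, gamma_categories, state_counts
from .simulate import CharacterMatrix
from .trees import Tree

__all__ = [
    "MCMCConfig",
    "PosteriorSample",
    "ConvergenceReport",
    "run_mcmc",
    "convergence_diagnostics",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings. Defaults are the desk-scale preset; the study's
    paper-scale preset uses :meth:`paper_scale`."""

    n_generations: int = 100_000
    sample_interval: int = 100
    n_runs: int = 2
    n_chains: int = 1  # >1 enables Metropolis coupling (1 cold + heated)
    burn_in_fraction: float = 0.25
    heating_lambda: float = 0.1  # beta_i = 1 / (1 + i * lambda)
    swap_interval: int = 1000
    move_weights: tuple[float, float, float, float] = (0.4, 0.1, 0.4, 0.1)
    branch_prior_rate: float = 10.0  # Exponential(10): prior mean length 0.1
    alpha_prior_rate: float = 1.0  # Exponential(1) on the gamma shape
    n_gamma_categories: int = 4
    alpha_grid_size: int = 121
    alpha_grid_range: tuple[float, float] = (0.02, 50.0)
    alpha_max_step: int = 6
    mult_lambda: float = 1.0  # branch multiplier tuning: exp(lambda*(u-1/2))
    ascertainment: str = "none"  # "none" | "variable" (Mkv)
    state_count_rule: str = "observed"
    start: str = "addition"  # "addition" | "random"
    flat_likelihood: bool = False  # prior-only sampling (validation)

    def __post_init__(self) -> None:
        if self.n_generations <= 0 or self.sample_interval <= 0:
            raise ValueError("generation counts must be positive")
        if self.n_generations % self.sample_interval:
            raise ValueError("sample_interval must divide n_generations")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_runs < 1 or self.n_chains < 1:
            raise ValueError("need at least one run and one chain")
        if any(w < 0 for w in self.move_weights) or sum(self.move_weights) <= 0:
            raise ValueError("move weights must be non-negative, not all zero")

    @classmethod
    def paper_scale(cls) -> "MCMCConfig":
        """The printed full-study settings: 1M generations, two runs, four
        Metropolis-coupled chains, every 100th sample stored."""
        return cls(n_generations=1_000_000, n_runs=2, n_chains=4)


@dataclass
class PosteriorSample:
    """Post burn-in posterior sample, runs combined.

    Topologies are stored in flat-array form; ``trees()`` materialises them
    lazily. ``n_per_run`` records how many retained samples came from each
    run so per-run diagnostics remain possible after combination.
    """

    labels: list[str]
    left: np.ndarray  # (n_samples, n_nodes)
    right: np.ndarray
    parent: np.ndarray
    blen: np.ndarray
    root: int
    alpha: np.ndarray  # (n_samples,)
    loglik: np.ndarray
    tree_length: np.ndarray
    n_per_run: list[int] = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.alpha)

    def tree(self, i: int) -> Tree:
        return Tree.from_arrays(
            self.left[i], self.right[i], self.parent[i], self.blen[i],
            self.root, self.labels,
        )

    def trees(self):
        for i in range(self.n_samples):
            yield self.tree(i)

    def split_counts(self, sl: slice | None = None) -> tuple[Counter, int]:
        """Canonical split-mask counts over (a slice of) the sample."""
        order = sorted(self.labels)
        bit = np.array([order.index(lab) for lab in self.labels])
        idx = range(self.n_samples)[sl] if sl is not None else range(self.n_samples)
        counts: Counter = Counter()
        n = len(self.labels)
        full = (1 << n) - 1
        anchor = 1 << order.index(order[0])
        post = np.empty(self.left.shape[1], np.int32)
        for i in idx:
            m = _kernels.postorder_fill(self.left[i], self.right[i], self.root, post)
            mask = [0] * self.left.shape[1]
            for jj in range(m):
                v = post[jj]
                if self.left[i][v] < 0:
                    mask[v] = 1 << int(bit[v])
                else:
                    mask[v] = mask[self.left[i][v]] | mask[self.right[i][v]]
            seen = set()
            for v in range(self.left.shape[1]):
                if v == self.root or self.left[i][v] < 0:
                    continue
                mm = mask[v]
                if mm & anchor:
                    mm = full ^ mm
                if bin(mm).count("1") >= 2 and bin(full ^ mm).count("1") >= 2:
                    seen.add(mm)
            counts.update(seen)
        return counts, len(list(idx))

    def split_frequencies(self, sl: slice | None = None) -> dict[int, float]:
        counts, n = self.split_counts(sl)
        return {m: c / n for m, c in counts.items()}

    def consensus(self, threshold: float = 0.5) -> Tree:
        counts, n = self.split_counts()
        return consensus_from_split_counts(counts, n, self.labels, threshold)

    def to_trees_text(self, sample_interval: int = 100) -> str:
        """Sampled trees as newick, one per line with a generation tag."""
        lines = []
        for i, t in enumerate(self.trees()):
            lines.append(f"[gen {(i + 1) * sample_interval}] "
                         + t.to_newick())
        return "\n".join(lines) + "\n"

    def trace_dataframe(self, sample_interval: int = 100):
        """Parameter trace (generation, logL, alpha, tree length)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": (np.arange(self.n_samples) + 1) * sample_interval,
                "loglik": self.loglik,
                "alpha": self.alpha,
                "tree_length": self.tree_length,
            }
        )


def _alpha_grid(config: MCMCConfig):
    lo, hi = config.alpha_grid_range
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), config.alpha_grid_size))
    # Exponential(rate) prior mass per grid cell (trapezoid cell widths)
    edges = np.empty(len(grid) + 1)
    edges[1:-1] = np.sqrt(grid[:-1] * grid[1:])
    edges[0], edges[-1] = grid[0], grid[-1]
    width = np.diff(edges)
    logprior = -config.alpha_prior_rate * grid + np.log(width)
    rates = np.stack(
        [gamma_categories(a, config.n_gamma_categories) for a in grid]
    )
    return grid, rates, logprior


def _start_state(matrix: CharacterMatrix, config: MCMCConfig, rng,
                 start_tree: Tree | None = None):
    n = matrix.n_taxa
    left = np.empty(2 * n - 1, np.int32)
    right = np.empty(2 * n - 1, np.int32)
    parent = np.empty(2 * n - 1, np.int32)
    if start_tree is not None:
        if sorted(start_tree.labels) != sorted(matrix.taxa):
            raise ValueError("start tree leaves must match the matrix taxa")
        if list(start_tree.labels) != list(matrix.taxa):
            # leaf ids must align with matrix rows: permute leaf indices
            perm = {old: matrix.taxa.index(lab)
                    for old, lab in enumerate(start_tree.labels)}
            perm.update({v: v for v in range(n, start_tree.n_nodes)})
            children = [[] for _ in range(start_tree.n_nodes)]
            parent_l = [-1] * start_tree.n_nodes
            blen_l = [0.0] * start_tree.n_nodes
            for v in range(start_tree.n_nodes):
                nv = perm[v]
                children[nv] = [perm[c] for c in start_tree.children[v]]
                parent_l[nv] = (perm[start_tree.parent[v]]
                                if start_tree.parent[v] >= 0 else -1)
                blen_l[nv] = start_tree.blen[v]
            start_tree = Tree(children, parent_l, blen_l, list(matrix.taxa),
                              perm[start_tree.root])
        arr = start_tree.as_arrays()
        left[:], right[:], parent[:] = arr.left, arr.right, arr.parent
        blen = np.maximum(arr.blen.copy(), 1e-8)
        root = int(arr.post[-1])
        blen[root] = 0.0
        return left, right, parent, blen, root
    if config.start == "addition":
        mask = np.where(
            matrix.states >= 0, np.left_shift(1, np.maximum(matrix.states, 0)), 15
        ).astype(np.uint8)
        ms = np.maximum(matrix.observed_state_counts() - 1, 0).astype(np.int64)
        order = rng.permutation(n).astype(np.int64)
        root, _, _ = _kernels.stepwise_addition(
            order, mask, ms, 0, 2.0, left, right, parent, rng.random(64)
        )
        root = int(root)
    else:
        from .trees import random_resolved_tree

        t = random_resolved_tree(matrix.taxa, rng)
        arr = t.as_arrays()
        left[:], right[:], parent[:] = arr.left, arr.right, arr.parent
        root = int(arr.post[-1])
    blen = rng.exponential(1.0 / config.branch_prior_rate, 2 * n - 1)
    blen[root] = 0.0
    return left, right, parent, blen, root


def _log_prior(blen, root, aidx, logprior_alpha, config):
    s = blen.sum() - blen[root]
    n_edges = len(blen) - 1
    return (
        n_edges * np.log(config.branch_prior_rate)
        - config.branch_prior_rate * s
        + logprior_alpha[aidx]
    )


def run_mcmc(
    matrix: CharacterMatrix,
    config: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    start_tree: Tree | None = None,
) -> PosteriorSample:
    """Sample the Mk+Gamma posterior for ``matrix``.

    Runs ``config.n_runs`` independent chains (each optionally Metropolis-
    coupled), discards the first ``burn_in_fraction`` of each run's stored
    samples and combines the rest. Deterministic given ``seed``.
    """
    if matrix.n_taxa < 4:
        raise ValueError("MCMC needs at least 4 taxa")
    tips = compact_states(matrix.states).astype(np.int8)
    kc = state_counts(matrix, config.state_count_rule)
    if config.ascertainment == "variable":
        raise NotImplementedError(
            "Mkv ascertainment in the sampler is handled through mk.mk_loglik "
            "based analyses; the study's simulated data uses plain Mk"
        )
    grid, rate_grid, alpha_logprior = _alpha_grid(config)
    move_w = np.asarray(config.move_weights, float)
    move_cum = np.cumsum(move_w / move_w.sum())
    n = matrix.n_taxa
    n_nodes = 2 * n - 1
    n_samples_run = config.n_generations // config.sample_interval

    kept_slices = []
    all_fields: dict[str, list] = {k: [] for k in
                                   ("left", "right", "parent", "blen", "alpha",
                                    "loglik", "treelen")}
    n_per_run = []
    acc_total = np.zeros(4, np.int64)
    prop_total = np.zeros(4, np.int64)
    root_common = None

    ss = np.random.SeedSequence(seed)
    for run in range(config.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(run,)))
        # chain states: index 0 is cold
        chains = []
        for ci in range(config.n_chains):
            left, right, parent, blen, root = _start_state(
                matrix, config, rng, start_tree
            )
            aidx = int(np.argmin(np.abs(grid - 1.0)))
            chains.append(
                {"left": left, "right": right, "parent": parent, "blen": blen,
                 "root": root, "aidx": aidx}
            )
        root_common = chains[0]["root"]
        betas = [1.0 / (1.0 + ci * config.heating_lambda)
                 for ci in range(config.n_chains)]

        sl = np.empty((n_samples_run, n_nodes), np.int32)
        sr = np.empty((n_samples_run, n_nodes), np.int32)
        sp = np.empty((n_samples_run, n_nodes), np.int32)
        sb = np.empty((n_samples_run, n_nodes), np.float64)
        sa = np.empty(n_samples_run, np.int32)
        sll = np.empty(n_samples_run, np.float64)
        stl = np.empty(n_samples_run, np.float64)

        if config.n_chains == 1:
            st = chains[0]
            acc = np.zeros(4, np.int64)
            prop = np.zeros(4, np.int64)
            kseed = int(rng.integers(2**31))
            ll, aidx = _kernels.mcmc_kernel(
                kseed, config.n_generations, config.sample_interval,
                st["left"], st["right"], st["parent"], st["blen"], st["root"],
                tips, kc, rate_grid, alpha_logprior, st["aidx"],
                config.branch_prior_rate, move_cum, config.mult_lambda,
                config.alpha_max_step, 1.0, config.flat_likelihood,
                sl, sr, sp, sb, sa, sll, stl, acc, prop,
            )
            acc_total += acc
            prop_total += prop
        else:
            # Metropolis coupling: advance each chain in blocks, then
            # propose a swap between a random adjacent temperature pair.
            n_blocks = max(config.n_generations // config.swap_interval, 1)
            block = config.n_generations // n_blocks
            spb = block // config.sample_interval
            dummy = [np.empty((max(spb, 1), n_nodes), np.int32),
                     np.empty((max(spb, 1), n_nodes), np.int32),
                     np.empty((max(spb, 1), n_nodes), np.int32),
                     np.empty((max(spb, 1), n_nodes), np.float64)]
            si = 0
            for b in range(n_blocks):
                lls = []
                for ci, st in enumerate(chains):
                    acc = np.zeros(4, np.int64)
                    prop = np.zeros(4, np.int64)
                    if ci == 0:
                        outs = (sl[si:si + spb], sr[si:si + spb],
                                sp[si:si + spb], sb[si:si + spb],
                                sa[si:si + spb], sll[si:si + spb],
                                stl[si:si + spb])
                    else:
                        outs = (dummy[0][:spb], dummy[1][:spb], dummy[2][:spb],
                                dummy[3][:spb], np.empty(spb, np.int32),
                                np.empty(spb, np.float64),
                                np.empty(spb, np.float64))
                    kseed = int(rng.integers(2**31))
                    ll, aidx = _kernels.mcmc_kernel(
                        kseed, block, config.sample_interval,
                        st["left"], st["right"], st["parent"], st["blen"],
                        st["root"], tips, kc, rate_grid, alpha_logprior,
                        st["aidx"], config.branch_prior_rate, move_cum,
                        config.mult_lambda, config.alpha_max_step,
                        betas[ci], config.flat_likelihood,
                        *outs, acc, prop,
                    )
                    st["aidx"] = int(aidx)
                    st["ll"] = float(ll)
                    lls.append(float(ll))
                    if ci == 0:
                        acc_total += acc
                        prop_total += prop
                si += spb
                if config.n_chains > 1:
                    i = int(rng.integers(config.n_chains - 1))
                    j = i + 1
                    lpost_i = lls[i] + _log_prior(
                        chains[i]["blen"], chains[i]["root"],
                        chains[i]["aidx"], alpha_logprior, config)
                    lpost_j = lls[j] + _log_prior(
                        chains[j]["blen"], chains[j]["root"],
                        chains[j]["aidx"], alpha_logprior, config)
                    log_r = (betas[i] - betas[j]) * (lpost_j - lpost_i)
                    if np.log(rng.random() + 1e-300) < log_r:
                        chains[i], chains[j] = chains[j], chains[i]

        burn = int(np.floor(n_samples_run * config.burn_in_fraction))
        keep = slice(burn, n_samples_run)
        all_fields["left"].append(sl[keep])
        all_fields["right"].append(sr[keep])
        all_fields["parent"].append(sp[keep])
        all_fields["blen"].append(sb[keep])
        all_fields["alpha"].append(grid[sa[keep]])
        all_fields["loglik"].append(sll[keep])
        all_fields["treelen"].append(stl[keep])
        n_per_run.append(n_samples_run - burn)

    props = np.maximum(prop_total, 1)
    acceptance = {
        name: acc_total[i] / props[i]
        for i, name in enumerate(("nni", "spr", "branch", "alpha"))
    }
    if acceptance["nni"] == 0 and not config.flat_likelihood:
        import warnings

        warnings.warn("no topology move was accepted; the chain may not mix",
                      stacklevel=2)
    return PosteriorSample(
        labels=list(matrix.taxa),
        left=np.concatenate(all_fields["left"]),
        right=np.concatenate(all_fields["right"]),
        parent=np.concatenate(all_fields["parent"]),
        blen=np.concatenate(all_fields["blen"]),
        root=int(root_common),
        alpha=np.concatenate(all_fields["alpha"]),
        loglik=np.concatenate(all_fields["loglik"]),
        tree_length=np.concatenate(all_fields["treelen"]),
        n_per_run=n_per_run,
        acceptance=acceptance,
    )


@dataclass(frozen=True)
class ConvergenceReport:
    asdsf: float
    psrf_alpha: float
    psrf_tree_length: float
    asdsf_threshold: float = 0.05
    psrf_threshold: float = 1.2

    @property
    def passed(self) -> bool:
        ok = self.asdsf < self.asdsf_threshold
        for v in (self.psrf_alpha, self.psrf_tree_length):
            if np.isfinite(v):
                ok = ok and v < self.psrf_threshold
        return bool(ok)


def _psrf(x1: np.ndarray, x2: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction for two chains."""
    m = min(len(x1), len(x2))
    if m < 2:
        return float("nan")
    chains = np.stack([x1[:m], x2[:m]])
    w = chains.var(axis=1, ddof=1).mean()
    b = m * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_hat = (m - 1) / m * w + b / m
    return float(np.sqrt(var_hat / w))


def convergence_diagnostics(
    sample_run1: PosteriorSample,
    sample_run2: PosteriorSample,
    asdsf_threshold: float = 0.05,
    psrf_threshold: float = 1.2,
    min_freq: float = 0.1,
) -> ConvergenceReport:
    """Between-run convergence: ASDSF over splits and PSRF for parameters.

    ASDSF is the average standard deviation of split frequencies across the
    two runs, over splits reaching ``min_freq`` in at least one run.
    """
    if sample_run1.labels != sample_run2.labels:
        raise ValueError("runs must come from identical configurations")
    f1 = sample_run1.split_frequencies()
    f2 = sample_run2.split_frequencies()
    splits = {m for m, f in f1.items() if f >= min_freq}
    splits |= {m for m, f in f2.items() if f >= min_freq}
    if splits:
        sds = [
            np.std([f1.get(m, 0.0), f2.get(m, 0.0)], ddof=1) for m in splits
        ]
        asdsf = float(np.mean(sds))
    else:
        asdsf = 0.0
    return ConvergenceReport(
        asdsf,
        _psrf(sample_run1.alpha, sample_run2.alpha),
        _psrf(sample_run1.tree_length, sample_run2.tree_length),
        asdsf_threshold,
        psrf_threshold,
    )
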
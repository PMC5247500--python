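"""Mk likelihood with discrete gamma rates, Mkv correction and ML search.

The Mk model (Lewis) is the k-state symmetric Markov chain: every state
change is equally likely and the stationary distribution is uniform. The
likelihood of a character is computed by Felsenstein pruning, averaged over
equal-probability discrete gamma rate categories. The Mkv variant divides
each character's likelihood by the probability of being variable,
correcting the acquisition bias of matrices that omit constant characters.

Maximum-likelihood search alternates per-edge branch-length optimisation
(Brent on the edge-wise likelihood computed from inside/outside partials),
bounded optimisation of the gamma shape, and greedy NNI moves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaincinv

from . import _kernels
from .simulate import CharacterMatrix
from .trees import Tree

__all__ = [
    "MkConfig",
    "MLResult",
    "mk_transition",
    "gamma_categories",
    "state_counts",
    "mk_loglik",
    "ml_search",
]


@dataclass(frozen=True)
class MkConfig:
    n_gamma_categories: int = 4
    ascertainment: str = "none"  # "none" | "variable" (Mkv)
    state_count_rule: str = "observed"  # "observed" | "by_type"
    min_branch: float = 1e-8
    max_branch: float = 50.0
    blen_xtol: float = 1e-6
    improve_tol: float = 1e-6  # minimum log-likelihood gain to accept a move
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.n_gamma_categories < 1:
            raise ValueError("need at least one gamma category")
        if self.ascertainment not in ("none", "variable"):
            raise ValueError("ascertainment must be 'none' or 'variable'")
        if self.state_count_rule not in ("observed", "by_type"):
            raise ValueError("state_count_rule must be 'observed' or 'by_type'")


@dataclass
class MLResult:
    tree: Tree
    alpha: float
    loglik: float
    n_iterations: int = 0


def mk_transition(t: float, k_states: int = 2, rate: float = 1.0) -> np.ndarray:
    """Mk transition matrix for branch length ``t`` at relative ``rate``.

    With tau = t * rate and the generator normalised to mean rate 1:
    P_same = 1/k + (k-1)/k * exp(-k tau / (k-1)), off-diagonals equal.
    """
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    k = int(k_states)
    if k < 2:
        raise ValueError("Mk needs at least 2 states")
    tau = t * rate
    e = np.exp(-k * tau / (k - 1))
    p_diff = (1.0 - e) / k
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def gamma_categories(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability bins of Gamma(alpha, alpha).

    Yang-style discretisation: bin boundaries are gamma quantiles and each
    category rate is the exact conditional mean within its bin; the rates
    are renormalised so their average is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if n_cat == 1:
        return np.ones(1)
    probs = np.arange(1, n_cat) / n_cat
    cuts = gammaincinv(alpha, probs) / alpha  # interior quantiles
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * cuts), [1.0]])
    lower = np.concatenate([[0.0], upper[:-1]])
    rates = n_cat * (upper - lower)
    return rates / rates.mean()


def state_counts(matrix: CharacterMatrix, rule: str = "observed") -> np.ndarray:
    """Per-character state count k_c used by the likelihood.

    ``observed``: number of distinct observed states, floored at 2 (the
    behaviour of standard-datatype likelihood programs). ``by_type``: fixed
    2 for binary and 4 for multistate characters.
    """
    if rule == "observed":
        return np.maximum(matrix.observed_state_counts(), 2).astype(np.int64)
    return np.where(matrix.is_binary, 2, 4).astype(np.int64)


def compact_states(states: np.ndarray) -> np.ndarray:
    """Relabel each character's observed states to consecutive 0..k-1.

    Under the symmetric Mk model relabelling does not change the likelihood,
    but the pruning kernels index states below the per-character count k_c,
    so e.g. a column with states {1,3} must become {0,1}.
    """
    out = states.copy()
    for j in range(states.shape[1]):
        col = states[:, j]
        vals = np.unique(col[col >= 0])
        if len(vals) and vals[-1] >= len(vals):
            for new, old in enumerate(vals):
                out[col == old, j] = new
    return out


def _tree_inputs(matrix: CharacterMatrix, tree: Tree, config: MkConfig):
    arr = tree.as_arrays()
    tips = compact_states(matrix.rows_for(tree.labels)).astype(np.int8)
    kc = state_counts(matrix, config.state_count_rule)
    return arr, tips, kc


def mk_loglik(
    matrix: CharacterMatrix,
    tree: Tree,
    alpha: float,
    config: MkConfig = MkConfig(),
) -> float:
    """Mk+Gamma log-likelihood of the matrix on a binary tree.

    Root state frequencies are uniform 1/k_c; with
    ``ascertainment="variable"`` each character's likelihood is divided by
    its probability of being variable (Mkv conditional likelihood).
    """
    arr, tips, kc = _tree_inputs(matrix, tree, config)
    rates = gamma_categories(alpha, config.n_gamma_categories)
    mkv = config.ascertainment == "variable"
    ll = _kernels.mk_loglik_arrays(
        arr.post, len(arr.post), arr.left, arr.right,
        np.maximum(arr.blen, 0.0), tips, kc, rates, mkv,
    )
    return float(ll)


# ---------------------------------------------------------------------------
# maximum-likelihood search
# ---------------------------------------------------------------------------


def _loglik_arrays(left, right, root, blen, tips, kc, rates, mkv):
    post = np.empty(left.shape[0], np.int32)
    m = _kernels.postorder_fill(left, right, root, post)
    return _kernels.mk_loglik_arrays(post, m, left, right, blen, tips, kc, rates, mkv)


def _edge_curves(left, right, root, blen, tips, kc, rates):
    """Per-edge sufficient statistics (U, S, D) for 1-D length optimisation.

    For edge above node v with inside partial ``down`` and outside partial
    ``up``: L(tau) per category is pd*U*S + (ps-pd)*D with U = sum(up),
    S = sum(down), D = sum(up*down).
    """
    n_nodes = left.shape[0]
    n_leaves = tips.shape[0]
    n_chars = tips.shape[1]
    ncat = rates.shape[0]
    post = np.empty(n_nodes, np.int32)
    m = _kernels.postorder_fill(left, right, root, post)
    down = np.empty((n_nodes - n_leaves, n_chars, ncat, 4))
    logscale = np.empty(n_chars)
    _kernels.mk_full_partials(
        post, m, left, right, blen, tips, kc, rates, down, logscale, False
    )
    up = np.zeros((n_nodes, n_chars, ncat, 4))
    pre = post[::-1].copy()
    _kernels.mk_up_partials(pre, m, left, right, blen, tips, kc, rates, down, up)
    kmask = np.arange(4)[None, None, :] < kc[:, None, None]  # (chars, 1, 4)
    # inside partials for every node: indicators at leaves, pruning elsewhere
    dn_all = np.empty((n_nodes, n_chars, ncat, 4))
    leaf_dn = np.zeros((n_leaves, n_chars, 1, 4))
    obs = tips >= 0
    li, ci = np.nonzero(obs)
    leaf_dn[li, ci, 0, tips[li, ci]] = 1.0
    leaf_dn[~obs] = 1.0
    dn_all[:n_leaves] = leaf_dn
    for v in range(n_leaves, n_nodes):
        dn_all[v] = down[v - n_leaves]
    up = np.where(kmask, up, 0.0)
    dn_all = np.where(kmask, dn_all, 0.0)
    uu = up.sum(axis=3)  # (nodes, chars, ncat)
    ss = dn_all.sum(axis=3)
    dd = (up * dn_all).sum(axis=3)
    return uu, ss, dd


def _edge_loglik(tau, uu, ss, dd, kc, rates):
    kk = kc[:, None].astype(float)
    e = np.exp(-kk * tau * rates[None, :] / (kk - 1.0))
    pd = (1.0 - e) / kk
    ps = 1.0 / kk + (kk - 1.0) / kk * e
    site = (pd * uu * ss + (ps - pd) * dd).mean(axis=1) / kc
    if np.any(site <= 0):
        return -np.inf
    return float(np.log(site).sum())


def _optimise_branch_lengths(left, right, parent, root, blen, tips, kc, rates,
                             config, n_passes=2):
    """Per-edge Brent updates from shared inside/outside partials.

    Partials are refreshed once per pass (Jacobi-style sweep); callers guard
    against the rare non-improving pass by comparing total log-likelihoods.
    """
    n_nodes = left.shape[0]
    for _ in range(n_passes):
        uu, ss, dd = _edge_curves(left, right, root, blen, tips, kc, rates)
        for v in range(n_nodes):
            if v == root:
                continue
            u_v, s_v, d_v = uu[v], ss[v], dd[v]
            res = optimize.minimize_scalar(
                lambda tau: -_edge_loglik(tau, u_v, s_v, d_v, kc, rates),
                bounds=(config.min_branch, config.max_branch),
                method="bounded",
                options={"xatol": config.blen_xtol},
            )
            blen[v] = float(res.x)
    return blen


def _optimise_alpha(left, right, root, blen, tips, kc, config, mkv, alpha0):
    def neg(log_a):
        rates = gamma_categories(float(np.exp(log_a)), config.n_gamma_categories)
        return -_loglik_arrays(left, right, root, blen, tips, kc, rates, mkv)

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(0.02), np.log(100.0)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _refine(left, right, parent, root, blen, tips, kc, config, mkv, alpha,
            max_rounds=12):
    """Alternate branch-length passes and shape optimisation to convergence.

    Keeps the best (branch lengths, alpha) state seen; returns
    (alpha, rates, loglik).
    """
    rates = gamma_categories(alpha, config.n_gamma_categories)
    best_ll = _loglik_arrays(left, right, root, blen, tips, kc, rates, mkv)
    best_blen, best_alpha = blen.copy(), alpha
    for _ in range(max_rounds):
        _optimise_branch_lengths(left, right, parent, root, blen, tips, kc,
                                 rates, config, n_passes=1)
        alpha = _optimise_alpha(left, right, root, blen, tips, kc, config,
                                mkv, alpha)
        rates = gamma_categories(alpha, config.n_gamma_categories)
        ll = _loglik_arrays(left, right, root, blen, tips, kc, rates, mkv)
        if ll > best_ll + config.improve_tol:
            best_ll, best_alpha = ll, alpha
            best_blen = blen.copy()
        else:
            break
    # joint polish along the (tree length, shape) ridge where coordinate
    # updates stall: rescale all branch lengths by exp(x0), shape exp(x1)
    def neg(x):
        rates = gamma_categories(float(np.exp(x[1])),
                                 config.n_gamma_categories)
        scaled = np.clip(best_blen * np.exp(x[0]), config.min_branch,
                         config.max_branch)
        return -_loglik_arrays(left, right, root, scaled, tips, kc, rates, mkv)

    r = optimize.minimize(neg, [0.0, np.log(best_alpha)],
                          method="Nelder-Mead",
                          options={"xatol": 1e-4, "fatol": 1e-8,
                                   "maxiter": 200})
    if -r.fun > best_ll:
        best_ll = -r.fun
        best_blen = np.clip(best_blen * np.exp(r.x[0]), config.min_branch,
                            config.max_branch)
        best_alpha = float(np.exp(r.x[1]))
    blen[:] = best_blen
    rates = gamma_categories(best_alpha, config.n_gamma_categories)
    return best_alpha, rates, best_ll


def ml_search(
    matrix: CharacterMatrix,
    config: MkConfig = MkConfig(),
    seed: int = 0,
) -> MLResult:
    """Greedy maximum-likelihood topology and parameter search.

    Starts from a random-addition parsimony tree, then alternates branch
    length optimisation, gamma-shape optimisation and best-improvement NNI
    until no move gains more than ``config.improve_tol`` log units. Returns
    the single best tree found (ML output is one fully resolved tree).
    """
    if matrix.n_taxa < 4:
        raise ValueError("ML search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    labels = list(matrix.taxa)
    n = len(labels)
    mkv = config.ascertainment == "variable"
    tips = compact_states(matrix.states).astype(np.int8)
    kc = state_counts(matrix, config.state_count_rule)

    # parsimony addition-sequence starting topology
    mask = np.where(
        matrix.states >= 0, np.left_shift(1, np.maximum(matrix.states, 0)), 15
    ).astype(np.uint8)
    ms = np.maximum(matrix.observed_state_counts() - 1, 0).astype(np.int64)
    left = np.empty(2 * n - 1, np.int32)
    right = np.empty(2 * n - 1, np.int32)
    parent = np.empty(2 * n - 1, np.int32)
    order = rng.permutation(n).astype(np.int64)
    root, _, _ = _kernels.stepwise_addition(
        order, mask, ms, 0, 2.0, left, right, parent, rng.random(64)
    )
    root = int(root)
    # cheap parsimony NNI polish: a near-optimal start saves likelihood sweeps
    _kernels.nni_hill_climb(left, right, parent, root, mask, ms, 0, 2.0, 50)
    blen = np.full(2 * n - 1, 0.1)
    blen[root] = 0.0

    alpha, rates, cur = _refine(left, right, parent, root, blen, tips, kc,
                                config, mkv, alpha=1.0)

    n_nodes = 2 * n - 1
    iters = 0
    for _ in range(config.max_iterations):
        iters += 1
        best_gain = 0.0
        best_move = None
        for v in range(n, n_nodes):
            if v == root or left[v] < 0:
                continue
            p = parent[v]
            s = right[p] if left[p] == v else left[p]
            for which in range(2):
                a = left[v] if which == 0 else right[v]
                _apply_nni(left, right, parent, v, p, a, s, which)
                ll = _loglik_arrays(left, right, root, blen, tips, kc, rates, mkv)
                _revert_nni(left, right, parent, v, p, a, s, which)
                gain = ll - cur
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_move = (v, p, a, s, which)
        if best_move is None or best_gain <= config.improve_tol:
            break
        v, p, a, s, which = best_move
        _apply_nni(left, right, parent, v, p, a, s, which)
        after_move = cur + best_gain
        old_blen, old_alpha = blen.copy(), alpha
        new_alpha, new_rates, new = _refine(left, right, parent, root, blen,
                                            tips, kc, config, mkv, alpha)
        if new >= after_move:
            alpha, rates, cur = new_alpha, new_rates, new
        else:  # keep the move but discard a non-improving optimisation pass
            blen[:] = old_blen
            alpha = old_alpha
            cur = after_move

    tree = Tree.from_arrays(left, right, parent, blen, root, labels)
    return MLResult(tree, alpha, float(cur), iters)


def _apply_nni(left, right, parent, v, p, a, s, which):
    if left[p] == s:
        left[p] = a
    else:
        right[p] = a
    if which == 0:
        left[v] = s
    else:
        right[v] = s
    parent[a] = p
    parent[s] = v


def _revert_nni(left, right, parent, v, p, a, s, which):
    if left[p] == a:
        left[p] = s
    else:
        right[p] = s
    if which == 0:
        left[v] = a
    else:
        right[v] = a
    parent[s] = p
    parent[a] = v
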
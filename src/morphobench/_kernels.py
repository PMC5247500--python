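"""Numba kernels: Fitch counting, Mk+Gamma pruning, tree search and MCMC.

All kernels operate on the flat binary-tree representation (``left``,
``right``, ``parent`` int32 arrays; ``blen`` float64; leaves ``0..n_leaves-1``).
Conditional likelihoods are stored only for internal nodes, indexed by
``node - n_leaves``, with a fixed state dimension of 4; per-character state
counts ``kc`` restrict all sums to the first ``kc[c]`` entries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# tree traversal
# ---------------------------------------------------------------------------


@njit(cache=True)
def postorder_fill(left, right, root, post):
    """Fill ``post`` with a postorder node sequence; returns node count."""
    n = post.shape[0]
    stack = np.empty(n, np.int32)
    top = 0
    stack[top] = root
    top += 1
    m = 0
    while top > 0:
        top -= 1
        v = stack[top]
        post[m] = v
        m += 1
        if left[v] >= 0:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    # reverse: parents currently precede children
    for i in range(m // 2):
        post[i], post[m - 1 - i] = post[m - 1 - i], post[i]
    return m


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


@njit(cache=True)
def fitch_counts(post, n_used, left, right, tips_mask, n_leaves, steps):
    """Per-character Fitch step counts on the tree given by ``post[:n_used]``.

    ``tips_mask``: uint8 state bitmasks per (leaf, character); 0b1111 for
    missing. ``steps`` is overwritten.
    """
    n_chars = tips_mask.shape[1]
    n_nodes = left.shape[0]
    state = np.empty((n_nodes, n_chars), np.uint8)
    for c in range(n_chars):
        steps[c] = 0
    for ii in range(n_used):
        v = post[ii]
        if left[v] < 0:
            for c in range(n_chars):
                state[v, c] = tips_mask[v, c]
        else:
            l, r = left[v], right[v]
            for c in range(n_chars):
                inter = state[l, c] & state[r, c]
                if inter == 0:
                    state[v, c] = state[l, c] | state[r, c]
                    steps[c] += 1
                else:
                    state[v, c] = inter


@njit(cache=True)
def parsimony_score(post, n_used, left, right, tips_mask, n_leaves, minsteps, mode, k):
    """EW (mode 0): total steps. IW (mode 1): sum of e/(e+k), e >= 0."""
    n_chars = tips_mask.shape[1]
    steps = np.empty(n_chars, np.int64)
    fitch_counts(post, n_used, left, right, tips_mask, n_leaves, steps)
    if mode == 0:
        total = 0.0
        for c in range(n_chars):
            total += steps[c]
        return total
    total = 0.0
    for c in range(n_chars):
        e = steps[c] - minsteps[c]
        if e < 0:
            e = 0
        total += e / (e + k)
    return total


@njit(cache=True)
def stepwise_addition(order, tips_mask, minsteps, mode, k, left, right, parent, rand_seq):
    """Greedy random-addition-sequence tree; returns (root, score).

    ``order``: leaf insertion order; ``rand_seq``: uniform deviates used for
    tie-breaking (one per insertion step is enough; indexed cyclically).
    Arrays ``left/right/parent`` are overwritten (size 2n-1).
    """
    n_leaves = tips_mask.shape[0]
    n_nodes = 2 * n_leaves - 1
    for v in range(n_nodes):
        left[v] = -1
        right[v] = -1
        parent[v] = -1
    post = np.empty(n_nodes, np.int32)
    # start: ((o0,o1),o2)
    a, b, c = order[0], order[1], order[2]
    cherry = n_leaves
    root = n_leaves + 1
    left[cherry] = a
    right[cherry] = b
    parent[a] = cherry
    parent[b] = cherry
    left[root] = cherry
    right[root] = c
    parent[cherry] = root
    parent[c] = root
    next_int = n_leaves + 2
    score = 0.0
    ri = 0
    n_eval = 0
    for oi in range(3, n_leaves):
        leaf = order[oi]
        best = np.inf
        best_edge = -1
        n_ties = 0
        for e in range(n_nodes):
            if e == root or parent[e] < 0:
                continue
            # tentatively insert leaf above e
            w = next_int
            p = parent[e]
            if left[p] == e:
                left[p] = w
            else:
                right[p] = w
            left[w] = e
            right[w] = leaf
            parent[w] = p
            parent[e] = w
            parent[leaf] = w
            m = postorder_fill(left, right, root, post)
            s = parsimony_score(post, m, left, right, tips_mask, n_leaves, minsteps, mode, k)
            n_eval += 1
            # revert
            if left[p] == w:
                left[p] = e
            else:
                right[p] = e
            parent[e] = p
            left[w] = -1
            right[w] = -1
            parent[w] = -1
            parent[leaf] = -1
            if s < best - 1e-12:
                best = s
                best_edge = e
                n_ties = 1
            elif s < best + 1e-12:
                n_ties += 1
                if rand_seq[ri % rand_seq.shape[0]] * n_ties < 1.0:
                    best_edge = e
                ri += 1
        # commit best insertion
        e = best_edge
        w = next_int
        next_int += 1
        p = parent[e]
        if left[p] == e:
            left[p] = w
        else:
            right[p] = w
        left[w] = e
        right[w] = leaf
        parent[w] = p
        parent[e] = w
        parent[leaf] = w
        score = best
    return root, score, n_eval


@njit(cache=True)
def nni_hill_climb(left, right, parent, root, tips_mask, minsteps, mode, k, max_rounds):
    """Greedy NNI hill climb on parsimony score; modifies arrays in place."""
    n_leaves = tips_mask.shape[0]
    n_nodes = left.shape[0]
    post = np.empty(n_nodes, np.int32)
    m = postorder_fill(left, right, root, post)
    cur = parsimony_score(post, m, left, right, tips_mask, n_leaves, minsteps, mode, k)
    n_eval = 1
    for _ in range(max_rounds):
        improved = False
        for v in range(n_leaves, n_nodes):
            if v == root or parent[v] < 0 or left[v] < 0:
                continue
            p = parent[v]
            s = right[p] if left[p] == v else left[p]
            for which in range(2):
                a = left[v] if which == 0 else right[v]
                # swap a <-> s
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
                m = postorder_fill(left, right, root, post)
                sc = parsimony_score(
                    post, m, left, right, tips_mask, n_leaves, minsteps, mode, k
                )
                n_eval += 1
                if sc < cur - 1e-9:
                    cur = sc
                    improved = True
                    s = a  # new sibling
                else:  # revert
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
        if not improved:
            break
    return cur, n_eval


@njit(cache=True)
def _collect_subtree(left, right, v, buf):
    n = 0
    stack = np.empty(buf.shape[0], np.int32)
    top = 0
    stack[top] = v
    top += 1
    while top > 0:
        top -= 1
        u = stack[top]
        buf[n] = u
        n += 1
        if left[u] >= 0:
            stack[top] = left[u]
            top += 1
            stack[top] = right[u]
            top += 1
    return n


@njit(cache=True)
def spr_hill_climb(left, right, parent, root, tips_mask, minsteps, mode, k, max_rounds):
    """Greedy hill climb over fixed-length SPR rearrangements."""
    n_leaves = tips_mask.shape[0]
    n_nodes = left.shape[0]
    post = np.empty(n_nodes, np.int32)
    buf = np.empty(n_nodes, np.int32)
    in_sub = np.zeros(n_nodes, np.uint8)
    m = postorder_fill(left, right, root, post)
    cur = parsimony_score(post, m, left, right, tips_mask, n_leaves, minsteps, mode, k)
    n_eval = 1
    for _ in range(max_rounds):
        improved = False
        for v in range(n_nodes):
            p = parent[v]
            if v == root or p < 0 or p == root:
                continue
            g = parent[p]
            s = right[p] if left[p] == v else left[p]
            cnt = _collect_subtree(left, right, v, buf)
            for i in range(n_nodes):
                in_sub[i] = 0
            for i in range(cnt):
                in_sub[buf[i]] = 1
            for t in range(n_nodes):
                if (
                    t == root
                    or parent[t] < 0
                    or in_sub[t] == 1
                    or t == p
                    or t == s
                ):
                    continue
                # detach p (s takes its place), reattach p onto edge above t
                if left[g] == p:
                    left[g] = s
                else:
                    right[g] = s
                parent[s] = g
                g2 = parent[t]
                if left[g2] == t:
                    left[g2] = p
                else:
                    right[g2] = p
                parent[p] = g2
                if left[p] == s:
                    left[p] = t
                else:
                    right[p] = t
                parent[t] = p
                m = postorder_fill(left, right, root, post)
                sc = parsimony_score(
                    post, m, left, right, tips_mask, n_leaves, minsteps, mode, k
                )
                n_eval += 1
                if sc < cur - 1e-9:
                    cur = sc
                    improved = True
                    g = parent[p]
                    s = right[p] if left[p] == v else left[p]
                else:  # revert
                    if left[g2] == p:
                        left[g2] = t
                    else:
                        right[g2] = t
                    parent[t] = g2
                    if left[g] == s:
                        left[g] = p
                    else:
                        right[g] = p
                    parent[p] = g
                    if left[p] == t:
                        left[p] = s
                    else:
                        right[p] = s
                    parent[s] = p
        if not improved:
            break
    return cur, n_eval


# ---------------------------------------------------------------------------
# Mk + discrete gamma likelihood
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _mk_update_node(v, left, right, blen, tips, kc, rates, partial, n_leaves):
    """Recompute the conditional likelihoods at internal node ``v``."""
    ncat = rates.shape[0]
    n_chars = tips.shape[1]
    row = partial[v - n_leaves]
    ps = np.empty((3, ncat))
    pd = np.empty((3, ncat))
    for ci in range(2):
        ch = left[v] if ci == 0 else right[v]
        b = blen[ch]
        for ki in range(3):
            kf = ki + 2.0
            for cat in range(ncat):
                e = np.exp(-kf * b * rates[cat] / (kf - 1.0))
                pd[ki, cat] = (1.0 - e) / kf
                ps[ki, cat] = 1.0 / kf + (kf - 1.0) / kf * e
        if ch < n_leaves:
            for c in range(n_chars):
                ki = kc[c] - 2
                kk = kc[c]
                s = tips[ch, c]
                for cat in range(ncat):
                    base = pd[ki, cat]
                    d = ps[ki, cat] - base
                    if ci == 0:
                        if s < 0:
                            for i in range(kk):
                                row[c, cat, i] = 1.0
                        else:
                            for i in range(kk):
                                row[c, cat, i] = base
                            row[c, cat, s] += d
                    else:
                        if s >= 0:
                            for i in range(kk):
                                row[c, cat, i] *= base if i != s else (base + d)
        else:
            crow = partial[ch - n_leaves]
            for c in range(n_chars):
                ki = kc[c] - 2
                kk = kc[c]
                for cat in range(ncat):
                    base = pd[ki, cat]
                    d = ps[ki, cat] - base
                    tot = 0.0
                    for j in range(kk):
                        tot += crow[c, cat, j]
                    if ci == 0:
                        for i in range(kk):
                            row[c, cat, i] = base * tot + d * crow[c, cat, i]
                    else:
                        for i in range(kk):
                            row[c, cat, i] *= base * tot + d * crow[c, cat, i]


@njit(cache=True, fastmath=True)
def _mk_root_loglik(partial, root, n_leaves, kc, ncat, per_char):
    """Total log-likelihood from the root row; fills per-char values too."""
    n_chars = kc.shape[0]
    row = partial[root - n_leaves]
    total = 0.0
    for c in range(n_chars):
        kk = kc[c]
        acc = 0.0
        for cat in range(ncat):
            s = 0.0
            for i in range(kk):
                s += row[c, cat, i]
            acc += s / kk
        acc /= ncat
        if acc <= 0.0 or not np.isfinite(acc):
            per_char[c] = -np.inf
            total = -np.inf
        else:
            per_char[c] = np.log(acc)
            total += per_char[c]
    return total


@njit(cache=True, fastmath=True)
def mk_full_partials(post, n_used, left, right, blen, tips, kc, rates, partial,
                     logscale, do_scale):
    """Postorder sweep filling all internal partials.

    With ``do_scale`` the partial at each node is rescaled by its maximum and
    the log factors accumulate per character in ``logscale``.
    """
    n_leaves = tips.shape[0]
    n_chars = tips.shape[1]
    ncat = rates.shape[0]
    for c in range(n_chars):
        logscale[c] = 0.0
    for ii in range(n_used):
        v = post[ii]
        if left[v] >= 0:
            _mk_update_node(v, left, right, blen, tips, kc, rates, partial, n_leaves)
            if do_scale:
                row = partial[v - n_leaves]
                for c in range(n_chars):
                    mx = 0.0
                    for cat in range(ncat):
                        for i in range(kc[c]):
                            if row[c, cat, i] > mx:
                                mx = row[c, cat, i]
                    if mx > 0.0 and mx < 1e-120:
                        inv = 1.0 / mx
                        for cat in range(ncat):
                            for i in range(kc[c]):
                                row[c, cat, i] *= inv
                        logscale[c] += np.log(mx)


@njit(cache=True, fastmath=True)
def mk_const_prob(post, n_used, left, right, blen, k, rates):
    """Probability that a k-state character is constant on the tree (Mkv)."""
    n_nodes = left.shape[0]
    ncat = rates.shape[0]
    part = np.empty((n_nodes, ncat, 4))
    for ii in range(n_used):
        v = post[ii]
        if left[v] < 0:
            for cat in range(ncat):
                for i in range(4):
                    part[v, cat, i] = 1.0 if i == 0 else 0.0
        else:
            for cat in range(ncat):
                for i in range(k):
                    part[v, cat, i] = 1.0
            for ci in range(2):
                ch = left[v] if ci == 0 else right[v]
                b = blen[ch]
                for cat in range(ncat):
                    e = np.exp(-k * b * rates[cat] / (k - 1.0))
                    base = (1.0 - e) / k
                    d = 1.0 / k + (k - 1.0) / k * e - base
                    tot = 0.0
                    for j in range(k):
                        tot += part[ch, cat, j]
                    for i in range(k):
                        part[v, cat, i] *= base * tot + d * part[ch, cat, i]
    root = post[n_used - 1]
    acc = 0.0
    for cat in range(ncat):
        s = 0.0
        for i in range(k):
            s += part[root, cat, i]
        acc += s / k
    acc /= ncat
    return k * acc  # k constant patterns, equal probability by symmetry


@njit(cache=True, fastmath=True)
def mk_loglik_arrays(post, n_used, left, right, blen, tips, kc, rates, mkv):
    """Scaled Mk+Gamma log-likelihood (optionally Mkv-conditioned)."""
    n_leaves = tips.shape[0]
    n_chars = tips.shape[1]
    ncat = rates.shape[0]
    n_internal = left.shape[0] - n_leaves
    partial = np.empty((n_internal, n_chars, ncat, 4))
    logscale = np.empty(n_chars)
    mk_full_partials(post, n_used, left, right, blen, tips, kc, rates, partial,
                     logscale, True)
    per_char = np.empty(n_chars)
    root = post[n_used - 1]
    total = _mk_root_loglik(partial, root, n_leaves, kc, ncat, per_char)
    if not np.isfinite(total):
        return -np.inf
    total = 0.0
    for c in range(n_chars):
        total += per_char[c] + logscale[c]
    if mkv:
        pconst = np.empty(5)
        for k in range(2, 5):
            pconst[k] = mk_const_prob(post, n_used, left, right, blen, k, rates)
        for c in range(n_chars):
            total -= np.log(1.0 - pconst[kc[c]])
    return total


@njit(cache=True, fastmath=True)
def mk_up_partials(pre, n_used, left, right, blen, tips, kc, rates, down, up):
    """Outside ('up') partials for every non-root node.

    ``up[v, c, cat, i]``: likelihood of all data outside the subtree of ``v``
    given state ``i`` at the parent end of the edge above ``v``. ``pre`` is a
    preorder sequence (root first). ``down`` holds internal partials from
    :func:`mk_full_partials` (unscaled).
    """
    n_leaves = tips.shape[0]
    n_chars = tips.shape[1]
    ncat = rates.shape[0]
    root = pre[0]
    ps = np.empty((3, ncat))
    pd = np.empty((3, ncat))
    tmp = np.empty(4)
    for ii in range(n_used):
        p = pre[ii]
        if left[p] < 0:
            continue
        for ci in range(2):
            v = left[p] if ci == 0 else right[p]
            s = right[p] if ci == 0 else left[p]
            # sibling contribution through sibling edge
            b = blen[s]
            for ki in range(3):
                kf = ki + 2.0
                for cat in range(ncat):
                    e = np.exp(-kf * b * rates[cat] / (kf - 1.0))
                    pd[ki, cat] = (1.0 - e) / kf
                    ps[ki, cat] = 1.0 / kf + (kf - 1.0) / kf * e
            for c in range(n_chars):
                kk = kc[c]
                ki = kk - 2
                for cat in range(ncat):
                    base = pd[ki, cat]
                    d = ps[ki, cat] - base
                    if s < n_leaves:
                        st = tips[s, c]
                        for i in range(kk):
                            if st < 0:
                                tmp[i] = 1.0
                            else:
                                tmp[i] = base + (d if i == st else 0.0)
                    else:
                        srow = down[s - n_leaves]
                        tot = 0.0
                        for j in range(kk):
                            tot += srow[c, cat, j]
                        for i in range(kk):
                            tmp[i] = base * tot + d * srow[c, cat, i]
                    for i in range(kk):
                        up[v, c, cat, i] = tmp[i]
            if p != root:
                # transform up[p] through the edge above p and fold in
                b2 = blen[p]
                for ki in range(3):
                    kf = ki + 2.0
                    for cat in range(ncat):
                        e = np.exp(-kf * b2 * rates[cat] / (kf - 1.0))
                        pd[ki, cat] = (1.0 - e) / kf
                        ps[ki, cat] = 1.0 / kf + (kf - 1.0) / kf * e
                for c in range(n_chars):
                    kk = kc[c]
                    ki = kk - 2
                    for cat in range(ncat):
                        base = pd[ki, cat]
                        d = ps[ki, cat] - base
                        tot = 0.0
                        for j in range(kk):
                            tot += up[p, c, cat, j]
                        for i in range(kk):
                            up[v, c, cat, i] *= base * tot + d * up[p, c, cat, i]


# ---------------------------------------------------------------------------
# Markov chain Monte Carlo under Mk + discrete gamma
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _backup_path(v0, left, parent, partial, scratch, path, n_leaves):
    """Save internal partial rows from ``v0`` up to the root; returns count."""
    cnt = 0
    v = v0
    while v >= 0:
        if left[v] >= 0:
            path[cnt] = v
            scratch[cnt] = partial[v - n_leaves]
            cnt += 1
        v = parent[v]
    return cnt


@njit(cache=True, fastmath=True)
def _recompute_path(path, cnt, left, right, blen, tips, kc, rates, partial, n_leaves):
    for i in range(cnt):
        _mk_update_node(path[i], left, right, blen, tips, kc, rates, partial, n_leaves)


@njit(cache=True, fastmath=True)
def _restore_path(path, cnt, partial, scratch, n_leaves):
    for i in range(cnt):
        partial[path[i] - n_leaves] = scratch[i]


@njit(cache=True, fastmath=True)
def mcmc_kernel(seed, n_gens, sample_interval,
                left, right, parent, blen, root,
                tips, kc, rate_grid, alpha_logprior, alpha_idx_init,
                br_rate, move_cum, mult_lambda, alpha_max_step,
                beta, flat_likelihood,
                samp_left, samp_right, samp_parent, samp_blen,
                samp_alpha_idx, samp_loglik, samp_treelen,
                accepts, proposals):
    """Metropolis-Hastings sampler over (topology, branch lengths, alpha).

    Moves: NNI, fixed-length SPR (both symmetric), branch-length multiplier,
    and a random walk on a precomputed alpha grid. ``beta`` heats the
    posterior (likelihood x prior) for Metropolis coupling; Hastings terms
    stay unheated. State arrays are modified in place; samples are written
    every ``sample_interval`` generations.
    """
    np.random.seed(seed)
    n_leaves = tips.shape[0]
    n_nodes = left.shape[0]
    n_internal = n_nodes - n_leaves
    n_chars = tips.shape[1]
    ncat = rate_grid.shape[1]
    n_alpha = rate_grid.shape[0]

    partial = np.empty((n_internal, n_chars, ncat, 4))
    scratch = np.empty((n_internal, n_chars, ncat, 4))
    post = np.empty(n_nodes, np.int32)
    path = np.empty(n_nodes, np.int32)
    sub = np.empty(n_nodes, np.int32)
    in_sub = np.zeros(n_nodes, np.uint8)
    per_char = np.empty(n_chars)
    save_l = np.empty(n_nodes, np.int32)
    save_r = np.empty(n_nodes, np.int32)
    save_p = np.empty(n_nodes, np.int32)

    aidx = alpha_idx_init
    rates = rate_grid[aidx].copy()

    m = postorder_fill(left, right, root, post)
    cur_ll = 0.0
    if not flat_likelihood:
        for ii in range(m):
            v = post[ii]
            if left[v] >= 0:
                _mk_update_node(v, left, right, blen, tips, kc, rates,
                                partial, n_leaves)
        cur_ll = _mk_root_loglik(partial, root, n_leaves, kc, ncat, per_char)

    si = 0
    for gen in range(n_gens):
        u = np.random.random()
        if u < move_cum[0]:
            # ---- NNI ----------------------------------------------------
            proposals[0] += 1
            v = n_leaves + np.int32(np.random.random() * n_internal)
            while v == root or v >= n_nodes:
                v = n_leaves + np.int32(np.random.random() * n_internal)
            p = parent[v]
            s = right[p] if left[p] == v else left[p]
            pick_left = np.random.random() < 0.5
            a = left[v] if pick_left else right[v]
            new_ll = cur_ll
            if flat_likelihood:
                cnt = 0
            else:
                cnt = _backup_path(v, left, parent, partial, scratch, path,
                                   n_leaves)
            # swap a <-> s
            if left[p] == s:
                left[p] = a
            else:
                right[p] = a
            if pick_left:
                left[v] = s
            else:
                right[v] = s
            parent[a] = p
            parent[s] = v
            if not flat_likelihood:
                _recompute_path(path, cnt, left, right, blen, tips, kc, rates,
                                partial, n_leaves)
                new_ll = _mk_root_loglik(partial, root, n_leaves, kc, ncat,
                                         per_char)
            if np.log(np.random.random() + 1e-300) < beta * (new_ll - cur_ll):
                cur_ll = new_ll
                accepts[0] += 1
            else:
                if left[p] == a:
                    left[p] = s
                else:
                    right[p] = s
                if pick_left:
                    left[v] = a
                else:
                    right[v] = a
                parent[s] = p
                parent[a] = v
                if not flat_likelihood:
                    _restore_path(path, cnt, partial, scratch, n_leaves)
        elif u < move_cum[1]:
            # ---- fixed-length SPR ---------------------------------------
            proposals[1] += 1
            # candidate prune nodes: non-root with non-root parent
            v = np.int32(np.random.random() * n_nodes)
            tries = 0
            while (v == root or parent[v] < 0 or parent[v] == root) and tries < 4 * n_nodes:
                v = np.int32(np.random.random() * n_nodes)
                tries += 1
            if v != root and parent[v] >= 0 and parent[v] != root:
                p = parent[v]
                g = parent[p]
                s = right[p] if left[p] == v else left[p]
                cnt_s = _collect_subtree(left, right, v, sub)
                for i in range(n_nodes):
                    in_sub[i] = 0
                for i in range(cnt_s):
                    in_sub[sub[i]] = 1
                # count valid targets
                nt = 0
                for t in range(n_nodes):
                    if t == root or parent[t] < 0 or in_sub[t] == 1 or t == p or t == s:
                        continue
                    nt += 1
                if nt > 0:
                    pick = np.int32(np.random.random() * nt)
                    t = -1
                    j = 0
                    for cand in range(n_nodes):
                        if cand == root or parent[cand] < 0 or in_sub[cand] == 1 \
                                or cand == p or cand == s:
                            continue
                        if j == pick:
                            t = cand
                            break
                        j += 1
                    # backup
                    for i in range(n_nodes):
                        save_l[i] = left[i]
                        save_r[i] = right[i]
                        save_p[i] = parent[i]
                    if not flat_likelihood:
                        scratch[:] = partial[:]
                    # detach p; s takes its place
                    if left[g] == p:
                        left[g] = s
                    else:
                        right[g] = s
                    parent[s] = g
                    g2 = parent[t]
                    if left[g2] == t:
                        left[g2] = p
                    else:
                        right[g2] = p
                    parent[p] = g2
                    if left[p] == s:
                        left[p] = t
                    else:
                        right[p] = t
                    parent[t] = p
                    new_ll = cur_ll
                    if not flat_likelihood:
                        m = postorder_fill(left, right, root, post)
                        for ii in range(m):
                            w = post[ii]
                            if left[w] >= 0:
                                _mk_update_node(w, left, right, blen, tips, kc,
                                                rates, partial, n_leaves)
                        new_ll = _mk_root_loglik(partial, root, n_leaves, kc,
                                                 ncat, per_char)
                    if np.log(np.random.random() + 1e-300) < beta * (new_ll - cur_ll):
                        cur_ll = new_ll
                        accepts[1] += 1
                    else:
                        for i in range(n_nodes):
                            left[i] = save_l[i]
                            right[i] = save_r[i]
                            parent[i] = save_p[i]
                        if not flat_likelihood:
                            partial[:] = scratch[:]
        elif u < move_cum[2]:
            # ---- branch-length multiplier -------------------------------
            proposals[2] += 1
            v = np.int32(np.random.random() * n_nodes)
            while v == root or parent[v] < 0:
                v = np.int32(np.random.random() * n_nodes)
            mult = np.exp(mult_lambda * (np.random.random() - 0.5))
            ob = blen[v]
            nb = ob * mult
            if 1e-8 < nb < 1e4:
                dprior = -br_rate * (nb - ob)
                if flat_likelihood:
                    cnt = 0
                else:
                    cnt = _backup_path(parent[v], left, parent, partial,
                                       scratch, path, n_leaves)
                blen[v] = nb
                new_ll = cur_ll
                if not flat_likelihood:
                    _recompute_path(path, cnt, left, right, blen, tips, kc,
                                    rates, partial, n_leaves)
                    new_ll = _mk_root_loglik(partial, root, n_leaves, kc, ncat,
                                             per_char)
                log_r = beta * (new_ll - cur_ll + dprior) + np.log(mult)
                if np.log(np.random.random() + 1e-300) < log_r:
                    cur_ll = new_ll
                    accepts[2] += 1
                else:
                    blen[v] = ob
                    if not flat_likelihood:
                        _restore_path(path, cnt, partial, scratch, n_leaves)
        else:
            # ---- alpha grid random walk ---------------------------------
            proposals[3] += 1
            step = 1 + np.int32(np.random.random() * alpha_max_step)
            if np.random.random() < 0.5:
                step = -step
            j = aidx + step
            if 0 <= j < n_alpha:
                dprior = alpha_logprior[j] - alpha_logprior[aidx]
                new_ll = cur_ll
                if not flat_likelihood:
                    scratch[:] = partial[:]
                    m = postorder_fill(left, right, root, post)
                    for ii in range(m):
                        w = post[ii]
                        if left[w] >= 0:
                            _mk_update_node(w, left, right, blen, tips, kc,
                                            rate_grid[j], partial, n_leaves)
                    new_ll = _mk_root_loglik(partial, root, n_leaves, kc, ncat,
                                             per_char)
                if np.log(np.random.random() + 1e-300) < beta * (new_ll - cur_ll + dprior):
                    cur_ll = new_ll
                    aidx = j
                    rates = rate_grid[aidx].copy()
                    accepts[3] += 1
                else:
                    if not flat_likelihood:
                        partial[:] = scratch[:]
        if (gen + 1) % sample_interval == 0:
            for i in range(n_nodes):
                samp_left[si, i] = left[i]
                samp_right[si, i] = right[i]
                samp_parent[si, i] = parent[i]
                samp_blen[si, i] = blen[i]
            samp_alpha_idx[si] = aidx
            samp_loglik[si] = cur_ll
            tl = 0.0
            for i in range(n_nodes):
                if i != root:
                    tl += blen[i]
            samp_treelen[si] = tl
            si += 1
    return cur_ll, aidx
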
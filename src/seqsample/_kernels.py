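"""Numba kernels for the O(n^2) column-wise probability update.

The column sweep is the inner loop of the sequential sampler: evaluating
individual i requires iterating over all previously evaluated individuals
k < i, bounding each preliminary weight so probabilities stay in [0, 1],
and subtracting (e_k - pi_k^(k-1)) * w_k, where e_k is the observed
participation indicator s_k or, while individual k's response is pending,
its estimated expectation phi_hat_k * b_k.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["column_sweep", "mc_pair_counts", "mc_inclusion_counts"]


@njit(cache=True)
def column_sweep(pi0_i, src_idx, src_w, e, pi_hist):  # pragma: no cover - jit
    """Run the bounded column-wise update for one target individual.

    Parameters
    ----------
    pi0_i : float
        Initial inclusion probability of the target.
    src_idx, src_w : int64[:], float64[:]
        Ascending indices k < i with nonzero preliminary weight, and the
        weights w~_k(i).
    e : float64[:]
        Effective outcome per source: s_k if resolved, phi_hat_k * b_k if
        pending (0 for non-invitees).
    pi_hist : float64[:]
        Stored pi_k^(k-1) for every already-evaluated k.
    """
    pi = pi0_i
    for t in range(src_idx.shape[0]):
        wt = src_w[t]
        if wt <= 0.0:
            continue
        k = src_idx[t]
        pk = pi_hist[k]
        ek = e[k]
        if ek == pk:
            continue  # update contribution is zero regardless of the bound
        if pk < 1.0:
            b1 = pi / (1.0 - pk)
        else:
            b1 = np.inf
        if pk > 0.0:
            b2 = (1.0 - pi) / pk
        else:
            b2 = np.inf
        w = wt
        if b1 < w:
            w = b1
        if b2 < w:
            w = b2
        pi -= (ek - pk) * w
        # the bounds keep pi in [0,1] exactly; guard round-off only
        if pi < 0.0:
            pi = 0.0
        elif pi > 1.0:
            pi = 1.0
    return pi


@njit(cache=True)
def _simple_run(pi0, w_const, phi, decisions, responses, pi_hist, e, sel,
                inv1, inv2):  # pragma: no cover - jit
    """One full run with constant uniform weights, known constant phi and
    immediate responses.  Returns the number selected; fills sel[:count].

    Same update arithmetic as :func:`column_sweep`, with the bound
    reciprocals 1/(1-pi_k) and 1/pi_k precomputed once per evaluated k so
    the O(n^2) inner loop is division-free.
    """
    n = pi0.shape[0]
    count = 0
    for i in range(n):
        pi = pi0[i]
        for k in range(i):
            pk = pi_hist[k]
            ek = e[k]
            if ek == pk:
                continue
            b1 = pi * inv1[k]
            b2 = (1.0 - pi) * inv2[k]
            w = w_const
            if b1 < w:
                w = b1
            if b2 < w:
                w = b2
            pi -= (ek - pk) * w
            if pi < 0.0:
                pi = 0.0
            elif pi > 1.0:
                pi = 1.0
        pi_hist[i] = pi
        inv1[i] = 1.0 / (1.0 - pi) if pi < 1.0 else np.inf
        inv2[i] = 1.0 / pi if pi > 0.0 else np.inf
        ptilde = pi / phi
        if ptilde > 1.0:
            ptilde = 1.0
        s = 0.0
        if decisions[i] < ptilde:  # invited
            if responses[i] < phi:  # participates, response immediate
                s = 1.0
        e[i] = s
        if s == 1.0:
            sel[count] = i
            count += 1
    return count


@njit(cache=True)
def mc_pair_counts(pi0, w_const, phi, n_runs, seed):  # pragma: no cover - jit
    """Joint selection counts over repeated runs (full-participation oracle).

    Used as the Monte-Carlo oracle for joint inclusion probabilities:
    counts[i, j] is the number of runs in which both i and j participated
    (the diagonal counts single inclusions).
    """
    np.random.seed(seed)
    n = pi0.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    pi_hist = np.empty(n)
    e = np.empty(n)
    sel = np.empty(n, dtype=np.int64)
    inv1 = np.empty(n)
    inv2 = np.empty(n)
    for _ in range(n_runs):
        decisions = np.random.random(n)
        responses = np.random.random(n)
        m = _simple_run(pi0, w_const, phi, decisions, responses, pi_hist, e, sel,
                        inv1, inv2)
        for a in range(m):
            ia = sel[a]
            counts[ia, ia] += 1
            for b in range(a + 1, m):
                ib = sel[b]
                counts[ia, ib] += 1
                counts[ib, ia] += 1
    return counts


@njit(cache=True)
def mc_inclusion_counts(pi0, w_const, phi, n_runs, seed):  # pragma: no cover - jit
    """First-order selection counts over repeated runs (known constant phi)."""
    np.random.seed(seed)
    n = pi0.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    pi_hist = np.empty(n)
    e = np.empty(n)
    sel = np.empty(n, dtype=np.int64)
    inv1 = np.empty(n)
    inv2 = np.empty(n)
    for _ in range(n_runs):
        decisions = np.random.random(n)
        responses = np.random.random(n)
        m = _simple_run(pi0, w_const, phi, decisions, responses, pi_hist, e, sel,
                        inv1, inv2)
        for a in range(m):
            counts[sel[a]] += 1
    return counts
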
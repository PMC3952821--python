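"""Banded dynamic-programming kernels over the alignment tensor.

All recursions run in the log domain on banded arrays of shape
``(Tx + 1, 2 W + 1, N)``: cell ``(i, k, s)`` holds the quantity for stimulus
position ``i``, response position ``j = i + k - W`` and state ``s``.  State
kinds are coded X=0 (consumes a stimulus symbol), R=1 (a response symbol),
M=2 (one of each).  Cell ``(0, 0)`` is the virtual start; paths begin with
the initial probabilities ``log_rho`` applied at the first consumption.

Emission inputs: ``logEx[i, s]`` for X-states at stimulus position ``i``
(1-based), ``logEr[j, s]`` for R-states at response position ``j``, and
``logEmv[i, v, s]`` for M-states joint with response symbol ``v``; ``robs``
is the 1-based observed response.

The kernels are jitted with numba when available; they are written as plain
nopython-compatible loops so the untouched Python versions remain correct
(just slow) without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


NEG_INF = -np.inf


@njit(cache=False)
def _logsumexp_pair(a, b):
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a > b:
        return a + np.log1p(np.exp(b - a))
    return b + np.log1p(np.exp(a - b))


@njit(cache=False)
def forward_kernel(kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, Tx, Tr, W, lagmin, lagmax):
    """Fill the forward tensor alpha; return (alpha, log_likelihood)."""
    N = kind.shape[0]
    alpha = np.full((Tx + 1, 2 * W + 1, N), NEG_INF)
    for i in range(Tx + 1):
        jlo = max(0, i - W)
        jhi = min(Tr, i + W)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            k = j - i + W
            for s in range(N):
                if j - i < lagmin[s] or j - i > lagmax[s]:
                    continue
                kd = kind[s]
                if kd == 0:
                    if i == 0:
                        continue
                    pi = i - 1
                    pj = j
                    e = logEx[i, s]
                elif kd == 1:
                    if j == 0:
                        continue
                    pi = i
                    pj = j - 1
                    e = logEr[j, s]
                else:
                    if i == 0 or j == 0:
                        continue
                    pi = i - 1
                    pj = j - 1
                    e = logEmv[i, robs[j], s]
                if e == NEG_INF:
                    continue
                pk = pj - pi + W
                if pk < 0 or pk > 2 * W:
                    continue
                if pi == 0 and pj == 0:
                    base = logrho[s]
                else:
                    base = NEG_INF
                    for sp in range(N):
                        t = alpha[pi, pk, sp] + logA[sp, s]
                        base = _logsumexp_pair(base, t)
                alpha[i, k, s] = base + e
    loglik = NEG_INF
    kend = Tr - Tx + W
    if 0 <= kend <= 2 * W:
        for s in range(N):
            loglik = _logsumexp_pair(loglik, alpha[Tx, kend, s] + logtau[s])
    return alpha, loglik


@njit(cache=False)
def backward_kernel(kind, logA, logtau, logEx, logEr, logEmv, robs, Tx, Tr, W, lagmin, lagmax):
    """Fill the backward tensor beta (beta at (Tx, Tr) is tau)."""
    N = kind.shape[0]
    beta = np.full((Tx + 1, 2 * W + 1, N), NEG_INF)
    kend = Tr - Tx + W
    if 0 <= kend <= 2 * W:
        for s in range(N):
            if Tr - Tx < lagmin[s] or Tr - Tx > lagmax[s]:
                continue
            beta[Tx, kend, s] = logtau[s]
    for i in range(Tx, -1, -1):
        jlo = max(0, i - W)
        jhi = min(Tr, i + W)
        for j in range(jhi, jlo - 1, -1):
            if i == Tx and j == Tr:
                continue
            k = j - i + W
            for s in range(N):
                acc = NEG_INF
                for sn in range(N):
                    kd = kind[sn]
                    if kd == 0:
                        ni = i + 1
                        nj = j
                        if ni > Tx:
                            continue
                        e = logEx[ni, sn]
                    elif kd == 1:
                        ni = i
                        nj = j + 1
                        if nj > Tr:
                            continue
                        e = logEr[nj, sn]
                    else:
                        ni = i + 1
                        nj = j + 1
                        if ni > Tx or nj > Tr:
                            continue
                        e = logEmv[ni, robs[nj], sn]
                    nk = nj - ni + W
                    if nk < 0 or nk > 2 * W:
                        continue
                    if nj - ni < lagmin[sn] or nj - ni > lagmax[sn]:
                        continue
                    t = logA[s, sn] + e + beta[ni, nk, sn]
                    acc = _logsumexp_pair(acc, t)
                beta[i, k, s] = acc
    return beta


@njit(cache=False)
def viterbi_kernel(kind, logA, logrho, logtau, logEx, logEr, logEmv, robs, Tx, Tr, W, lagmin, lagmax):
    """Max-product recursion; returns (delta, pointer, best_end_state, log_prob).

    ``pointer[i, k, s]`` is the best precursor state index (-1 at the start).
    Ties break toward the lowest precursor index.
    """
    N = kind.shape[0]
    delta = np.full((Tx + 1, 2 * W + 1, N), NEG_INF)
    ptr = np.full((Tx + 1, 2 * W + 1, N), -2, dtype=np.int64)
    for i in range(Tx + 1):
        jlo = max(0, i - W)
        jhi = min(Tr, i + W)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            k = j - i + W
            for s in range(N):
                if j - i < lagmin[s] or j - i > lagmax[s]:
                    continue
                kd = kind[s]
                if kd == 0:
                    if i == 0:
                        continue
                    pi = i - 1
                    pj = j
                    e = logEx[i, s]
                elif kd == 1:
                    if j == 0:
                        continue
                    pi = i
                    pj = j - 1
                    e = logEr[j, s]
                else:
                    if i == 0 or j == 0:
                        continue
                    pi = i - 1
                    pj = j - 1
                    e = logEmv[i, robs[j], s]
                if e == NEG_INF:
                    continue
                pk = pj - pi + W
                if pk < 0 or pk > 2 * W:
                    continue
                if pi == 0 and pj == 0:
                    best = logrho[s]
                    arg = -1
                else:
                    best = NEG_INF
                    arg = -2
                    for sp in range(N):
                        t = delta[pi, pk, sp] + logA[sp, s]
                        if t > best:
                            best = t
                            arg = sp
                if arg == -2:
                    continue
                delta[i, k, s] = best + e
                ptr[i, k, s] = arg
    kend = Tr - Tx + W
    best_end = -1
    best_val = NEG_INF
    if 0 <= kend <= 2 * W:
        for s in range(N):
            t = delta[Tx, kend, s] + logtau[s]
            if t > best_val:
                best_val = t
                best_end = s
    return delta, ptr, best_end, best_val


@njit(cache=False)
def transition_stats_kernel(
    kind, logA, logEx, logEr, logEmv, robs, Tx, Tr, W, alpha, beta, loglik, lagmin, lagmax
):
    """Expected transition counts xi summed over all banded positions.

    Returns the (N, N) matrix of expected transitions s -> s'.
    """
    N = kind.shape[0]
    xiA = np.zeros((N, N))
    for i in range(Tx + 1):
        jlo = max(0, i - W)
        jhi = min(Tr, i + W)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            k = j - i + W
            for s in range(N):
                a = alpha[i, k, s]
                if a == NEG_INF:
                    continue
                for sn in range(N):
                    kd = kind[sn]
                    if kd == 0:
                        ni = i + 1
                        nj = j
                        if ni > Tx:
                            continue
                        e = logEx[ni, sn]
                    elif kd == 1:
                        ni = i
                        nj = j + 1
                        if nj > Tr:
                            continue
                        e = logEr[nj, sn]
                    else:
                        ni = i + 1
                        nj = j + 1
                        if ni > Tx or nj > Tr:
                            continue
                        e = logEmv[ni, robs[nj], sn]
                    if e == NEG_INF:
                        continue
                    nk = nj - ni + W
                    if nk < 0 or nk > 2 * W:
                        continue
                    if nj - ni < lagmin[sn] or nj - ni > lagmax[sn]:
                        continue
                    b = beta[ni, nk, sn]
                    if b == NEG_INF:
                        continue
                    xiA[s, sn] += np.exp(a + logA[s, sn] + e + b - loglik)
    return xiA


@njit(cache=False)
def encode_kernel(kind, logA, logrho, logtau, logEx, logPr, logEmv, Tx, Tr, W, lagmin, lagmax):
    """Extended Viterbi over (path, response): response symbols chosen per cell.

    ``logPr[s, v]`` are R-state symbol log probabilities; ``logEmv[i, v, s]``
    the joint M-state emissions.  At each R/M cell the symbol maximizing the
    emission is taken and recorded in ``sym``; backtracking recovers the
    jointly most likely (state path, response) pair.
    """
    N = kind.shape[0]
    V = logPr.shape[1]
    delta = np.full((Tx + 1, 2 * W + 1, N), NEG_INF)
    ptr = np.full((Tx + 1, 2 * W + 1, N), -2, dtype=np.int64)
    sym = np.full((Tx + 1, 2 * W + 1, N), -1, dtype=np.int64)
    for i in range(Tx + 1):
        jlo = max(0, i - W)
        jhi = min(Tr, i + W)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            k = j - i + W
            for s in range(N):
                if j - i < lagmin[s] or j - i > lagmax[s]:
                    continue
                kd = kind[s]
                bestv = -1
                if kd == 0:
                    if i == 0:
                        continue
                    pi = i - 1
                    pj = j
                    e = logEx[i, s]
                elif kd == 1:
                    if j == 0:
                        continue
                    pi = i
                    pj = j - 1
                    e = NEG_INF
                    for v in range(V):
                        if logPr[s, v] > e:
                            e = logPr[s, v]
                            bestv = v
                else:
                    if i == 0 or j == 0:
                        continue
                    pi = i - 1
                    pj = j - 1
                    e = NEG_INF
                    for v in range(V):
                        if logEmv[i, v, s] > e:
                            e = logEmv[i, v, s]
                            bestv = v
                if e == NEG_INF:
                    continue
                pk = pj - pi + W
                if pk < 0 or pk > 2 * W:
                    continue
                if pi == 0 and pj == 0:
                    best = logrho[s]
                    arg = -1
                else:
                    best = NEG_INF
                    arg = -2
                    for sp in range(N):
                        t = delta[pi, pk, sp] + logA[sp, s]
                        if t > best:
                            best = t
                            arg = sp
                if arg == -2:
                    continue
                delta[i, k, s] = best + e
                ptr[i, k, s] = arg
                sym[i, k, s] = bestv
    kend = Tr - Tx + W
    best_end = -1
    best_val = NEG_INF
    if 0 <= kend <= 2 * W:
        for s in range(N):
            t = delta[Tx, kend, s] + logtau[s]
            if t > best_val:
                best_val = t
                best_end = s
    return delta, ptr, sym, best_end, best_val
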
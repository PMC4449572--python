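"""Sparse LDL' factorization with Takahashi selected inverse.

Pedigree mixed-model equations are extremely sparse (the pedigree inverse
couples each animal only to parents, progeny and mates), and EM-REML needs
only selected entries of the inverse coefficient matrix: the diagonal
blocks, the entries on the sparsity pattern of A^-1, and the dense
fixed-effect border.  The classical machinery for this is an up-looking
sparse LDL' factorization (elimination tree + ereach, CSparse-style)
followed by the Takahashi equations, which compute the inverse exactly on
the filled pattern of the factor.  Everything here is numba-compiled and
operates on CSC arrays; the symbolic analysis is done once per pattern.

The fixed-effect equations are dense and are handled by the caller as a
trailing dense border via Schur complement.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "symbolic",
    "numeric_ldl",
    "takahashi",
    "ldl_solve",
    "ldl_solve_multi",
    "lookup",
]


@njit(cache=True)
def _etree(n, Ap, Ai):
    parent = np.full(n, -1, np.int64)
    ancestor = np.full(n, -1, np.int64)
    for j in range(n):
        for p in range(Ap[j], Ap[j + 1]):
            i = Ai[p]
            while i != -1 and i < j:
                inext = ancestor[i]
                ancestor[i] = j
                if inext == -1:
                    parent[i] = j
                i = inext
    return parent


@njit(cache=True)
def _ereach(k, Ap, Ai, parent, mark, stack):
    """Pattern of row k of L as stack[top:n], topologically ordered."""
    n = len(parent)
    top = n
    mark[k] = k
    for p in range(Ap[k], Ap[k + 1]):
        i = Ai[p]
        if i >= k:
            continue
        ln = 0
        while mark[i] != k:
            stack[ln] = i
            ln += 1
            mark[i] = k
            i = parent[i]
        while ln > 0:
            ln -= 1
            top -= 1
            stack[top] = stack[ln]
    return top


@njit(cache=True)
def symbolic(n, Ap, Ai):
    """Column pointers and row indices of L (no values), plus the etree."""
    parent = _etree(n, Ap, Ai)
    mark = np.full(n, -1, np.int64)
    stack = np.empty(n, np.int64)
    counts = np.zeros(n, np.int64)
    for k in range(n):
        top = _ereach(k, Ap, Ai, parent, mark, stack)
        for p in range(top, n):
            counts[stack[p]] += 1
    Lp = np.zeros(n + 1, np.int64)
    for j in range(n):
        Lp[j + 1] = Lp[j] + counts[j]
    Li = np.empty(Lp[n], np.int64)
    nxt = Lp[:n].copy()
    mark[:] = -1
    for k in range(n):
        top = _ereach(k, Ap, Ai, parent, mark, stack)
        for p in range(top, n):
            j = stack[p]
            Li[nxt[j]] = k
            nxt[j] += 1
    return Lp, Li, parent


@njit(cache=True)
def numeric_ldl(n, Ap, Ai, Ax, Lp, Li, parent):
    """Up-looking LDL' using a precomputed symbolic pattern.

    Returns (Lx, d).  Row indices within each column of L arrive in
    increasing order because rows are processed in order.
    """
    Lx = np.zeros(len(Li))
    d = np.zeros(n)
    fill = Lp[:n].copy()  # next free slot per column
    x = np.zeros(n)
    mark = np.full(n, -1, np.int64)
    stack = np.empty(n, np.int64)
    for k in range(n):
        top = _ereach(k, Ap, Ai, parent, mark, stack)
        dk = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                x[i] = Ax[p]
            elif i == k:
                dk = Ax[p]
        for p in range(top, n):
            j = stack[p]
            y = x[j]
            x[j] = 0.0
            for q in range(Lp[j], fill[j]):
                x[Li[q]] -= Lx[q] * y
            lkj = y / d[j]
            dk -= lkj * y
            Lx[fill[j]] = lkj
            fill[j] += 1
        if dk <= 0.0:
            raise np.linalg.LinAlgError  # not positive definite
        d[k] = dk
    return Lx, d


@njit(cache=True)
def lookup(Lp, Li, col, row):
    """Index of entry (row, col) in CSC arrays, -1 if absent (binary search)."""
    lo = Lp[col]
    hi = Lp[col + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = Li[mid]
        if v == row:
            return mid
        if v < row:
            lo = mid + 1
        else:
            hi = mid
    return -1


@njit(cache=True)
def takahashi(n, Lp, Li, Lx, d):
    """Selected inverse Z = (L D L')^-1 on the pattern of L (plus diagonal).

    Processes columns from last to first.  For column j the needed block
    Z[S_j, S_j] lies entirely on the already-computed pattern (the classic
    fill path property), and is gathered by scanning the stored columns of
    the members with a scatter workspace instead of per-entry searches.
    """
    Zx = np.zeros(len(Li))
    Zd = np.zeros(n)
    w = np.full(n, -1, np.int64)
    maxm = 0
    for j in range(n):
        m = Lp[j + 1] - Lp[j]
        if m > maxm:
            maxm = m
    M = np.zeros((maxm, maxm))
    z = np.zeros(maxm)
    for j in range(n - 1, -1, -1):
        lo, hi = Lp[j], Lp[j + 1]
        m = hi - lo
        if m == 0:
            Zd[j] = 1.0 / d[j]
            continue
        for a in range(m):
            w[Li[lo + a]] = a
        for b in range(m):
            k = Li[lo + b]
            M[b, b] = Zd[k]
            for q in range(Lp[k], Lp[k + 1]):
                a = w[Li[q]]
                if a >= 0:
                    M[a, b] = Zx[q]
                    M[b, a] = Zx[q]
        for a in range(m):
            acc = 0.0
            for b in range(m):
                acc -= M[a, b] * Lx[lo + b]
            z[a] = acc
        zjj = 1.0 / d[j]
        for b in range(m):
            Zx[lo + b] = z[b]
            zjj -= Lx[lo + b] * z[b]
        Zd[j] = zjj
        for a in range(m):
            w[Li[lo + a]] = -1
    return Zx, Zd


@njit(cache=True)
def assemble_block_values(Ap, Ai, Av, Ga_inv, se2, Fdiag):
    """Scalar CSC values for C = blockdiag(F) + se2 * (Ainv x Ga_inv).

    The scalar pattern must have been expanded from the animal CSC in the
    same deterministic order (per animal column: three scalar columns, each
    listing rows 3m+a for the animal rows m in order).
    """
    nA = len(Ap) - 1
    total = 0
    for ncol in range(nA):
        total += 3 * (Ap[ncol + 1] - Ap[ncol])
    Cx = np.empty(3 * total)
    idx = 0
    for ncol in range(nA):
        for b in range(3):
            for p in range(Ap[ncol], Ap[ncol + 1]):
                m = Ai[p]
                v = Av[p] * se2
                for a in range(3):
                    val = v * Ga_inv[a, b]
                    if m == ncol:
                        val += Fdiag[ncol, a, b]
                    Cx[idx] = val
                    idx += 1
    return Cx


@njit(cache=True)
def _inv_entry(i, j, Lp, Li, Zx, Zd):
    if i == j:
        return Zd[i]
    if i > j:
        q = lookup(Lp, Li, j, i)
    else:
        q = lookup(Lp, Li, i, j)
    return Zx[q] if q >= 0 else 0.0


@njit(cache=True)
def weighted_block_trace(Ap, Ai, Av, Lp, Li, Zx, Zd, Q):
    """T[a,b] = sum over animal-pattern entries v_mn * Cinv[3m+a, 3n+b].

    Cinv = Takahashi inverse of the genetic block plus the dense-border
    correction Q Q' (Q = W L_s^-T from the Schur complement).
    """
    T = np.zeros((3, 3))
    nA = len(Ap) - 1
    nq = Q.shape[1]
    for ncol in range(nA):
        for p in range(Ap[ncol], Ap[ncol + 1]):
            m = Ai[p]
            v = Av[p]
            for a in range(3):
                i = 3 * m + a
                for b in range(3):
                    j = 3 * ncol + b
                    z = _inv_entry(i, j, Lp, Li, Zx, Zd)
                    corr = 0.0
                    for r in range(nq):
                        corr += Q[i, r] * Q[j, r]
                    T[a, b] += v * (z + corr)
    return T


@njit(cache=True)
def diag_blocks(members, Lp, Li, Zx, Zd):
    """3x3 diagonal blocks of the Takahashi inverse for listed animals."""
    out = np.zeros((len(members), 3, 3))
    for t in range(len(members)):
        m = members[t]
        for a in range(3):
            for b in range(3):
                out[t, a, b] = _inv_entry(3 * m + a, 3 * m + b, Lp, Li, Zx, Zd)
    return out


@njit(cache=True)
def ldl_solve(Lp, Li, Lx, d, b):
    """Solve (L D L') x = b on a copy of the 1-D right-hand side."""
    n = len(d)
    x = b.copy()
    for j in range(n):
        xj = x[j]
        for q in range(Lp[j], Lp[j + 1]):
            x[Li[q]] -= Lx[q] * xj
    for j in range(n):
        x[j] /= d[j]
    for j in range(n - 1, -1, -1):
        acc = x[j]
        for q in range(Lp[j], Lp[j + 1]):
            acc -= Lx[q] * x[Li[q]]
        x[j] = acc
    return x


@njit(cache=True)
def ldl_solve_multi(Lp, Li, Lx, d, B):
    """Column-wise (L D L') solve for a 2-D right-hand side."""
    n = len(d)
    X = B.copy()
    nrhs = X.shape[1]
    for j in range(n):
        for q in range(Lp[j], Lp[j + 1]):
            i = Li[q]
            l = Lx[q]
            for r in range(nrhs):
                X[i, r] -= l * X[j, r]
    for j in range(n):
        dj = d[j]
        for r in range(nrhs):
            X[j, r] /= dj
    for j in range(n - 1, -1, -1):
        for q in range(Lp[j], Lp[j + 1]):
            i = Li[q]
            l = Lx[q]
            for r in range(nrhs):
                X[j, r] -= l * X[i, r]
    return X
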
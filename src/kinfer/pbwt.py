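"""Positional Burrows-Wheeler transform long-match scanning.

Finds every maximal exact match of at least ``min_length`` columns between
any two rows of a binary matrix in time roughly linear in the matrix size
plus the output size, without all-pairs comparison.  The positional prefix
array keeps haplotypes sorted by their reversed prefixes; the companion
divergence array records, for each adjacent pair in that order, where
their current match began.  A match is reported when it terminates —
either the two rows disagree at the next column, or the matrix ends.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _scan_long_matches(Hc: np.ndarray, L: int, out: np.ndarray) -> int:  # pragma: no cover
    """Core scan.  ``Hc`` is column-major ``(M, N)`` uint8; writes rows
    ``(row_i, row_j, start, end)`` into ``out`` and returns the total match
    count (which may exceed ``out``'s capacity; extra matches are counted
    but not written, the caller re-runs with a bigger buffer)."""
    M, N = Hc.shape
    cap = out.shape[0]
    ppa = np.empty(N, dtype=np.int64)
    div = np.zeros(N, dtype=np.int64)
    a = np.empty(N, dtype=np.int64)
    b = np.empty(N, dtype=np.int64)
    d0 = np.empty(N, dtype=np.int64)
    d1 = np.empty(N, dtype=np.int64)
    for i in range(N):
        ppa[i] = i
    count = 0
    for k in range(M + 1):
        # --- report matches of length >= L terminating at column k ---
        # blocks are maximal runs whose internal divergences are <= k - L
        lo = 0
        while lo < N:
            hi = lo + 1
            while hi < N and div[hi] <= k - L:
                hi += 1
            if hi - lo >= 2:
                for v in range(lo + 1, hi):
                    mx = np.int64(0)
                    for u in range(v - 1, lo - 1, -1):
                        if div[u + 1] > mx:
                            mx = div[u + 1]
                        x = ppa[u]
                        y = ppa[v]
                        if k == M or Hc[k, x] != Hc[k, y]:
                            if count < cap:
                                if x < y:
                                    out[count, 0] = x
                                    out[count, 1] = y
                                else:
                                    out[count, 0] = y
                                    out[count, 1] = x
                                out[count, 2] = mx
                                out[count, 3] = k
                            count += 1
            lo = hi
        if k == M:
            break
        # --- extend prefix/divergence arrays to column k + 1 ---
        p = k + 1
        q = k + 1
        na = 0
        nb = 0
        for i in range(N):
            d = div[i]
            if d > p:
                p = d
            if d > q:
                q = d
            x = ppa[i]
            if Hc[k, x] == 0:
                a[na] = x
                d0[na] = p
                na += 1
                p = 0
            else:
                b[nb] = x
                d1[nb] = q
                nb += 1
                q = 0
        for i in range(na):
            ppa[i] = a[i]
            div[i] = d0[i]
        for i in range(nb):
            ppa[na + i] = b[i]
            div[na + i] = d1[i]
        div[0] = k + 1  # sentinel: no match precedes the first row
    return count


def pbwt_long_matches(matrix: np.ndarray, min_length: int) -> list[tuple[int, int, int, int]]:
    """All maximal exact matches of >= ``min_length`` columns between rows.

    Parameters
    ----------
    matrix
        ``(N, M)`` array of {0, 1} (rows = haplotypes, columns = sites or
        projected windows).
    min_length
        Minimum match length in columns.

    Returns
    -------
    list of ``(row_i, row_j, start, end)`` with ``row_i < row_j`` and the
    match covering columns ``[start, end)``; sorted for determinism.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    H = np.ascontiguousarray(matrix, dtype=np.uint8)
    N, M = H.shape
    if N < 2 or M < min_length:
        return []
    Hc = np.ascontiguousarray(H.T)
    cap = max(4 * N + 1024, 1 << 14)
    while True:
        out = np.empty((cap, 4), dtype=np.int64)
        n = _scan_long_matches(Hc, min_length, out)
        if n <= cap:
            break
        cap = int(n) + 1024
    res = out[:n]
    order = np.lexsort((res[:, 2], res[:, 1], res[:, 0]))
    return [tuple(int(v) for v in row) for row in res[order]]
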
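"""Numerical kernels for template counting and neighbor search.

The O(N^2) inner loops are compiled with numba when available; a chunked
numpy implementation provides the identical (bit-for-bit) fallback. Both
paths are checked against explicit brute-force oracles in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


# ---------------------------------------------------------------------------
# Entropy template counting
#
# Templates are indexed by their final point n = m .. N-1 (0-based). For each
# n the m-point past vector is x[n-m:n] and the (m+1)-point joint vector is
# x[n-m:n+1]. B[n] counts indices j (self included) whose past vector is
# within r in Chebyshev distance; A[n] the same for the joint vector.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _entropy_counts_nb(x, m, r):  # pragma: no cover - compiled
    n_t = x.shape[0] - m
    a = np.zeros(n_t, dtype=np.int64)
    b = np.zeros(n_t, dtype=np.int64)
    for i in range(n_t):
        for j in range(n_t):
            dp = 0.0
            for k in range(m):
                d = abs(x[i + k] - x[j + k])
                if d > dp:
                    dp = d
                    if dp > r:
                        break
            if dp <= r:
                b[i] += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a[i] += 1
    return a, b


def _entropy_counts_np(x: np.ndarray, m: int, r: float):
    n_t = len(x) - m
    idx = np.arange(n_t)[:, None] + np.arange(m + 1)[None, :]
    emb = x[idx]  # (n_t, m+1); row i = joint template ending at i + m
    past = emb[:, :m]
    last = emb[:, m]
    a = np.empty(n_t, dtype=np.int64)
    b = np.empty(n_t, dtype=np.int64)
    chunk = max(1, int(2_000_000 // max(n_t, 1)))
    for s in range(0, n_t, chunk):
        e = min(s + chunk, n_t)
        dp = np.abs(past[s:e, None, :] - past[None, :, :]).max(axis=2)
        close_past = dp <= r
        b[s:e] = close_past.sum(axis=1)
        dl = np.abs(last[s:e, None] - last[None, :])
        a[s:e] = (close_past & (dl <= r)).sum(axis=1)
    return a, b


def entropy_counts(x: np.ndarray, m: int, r: float):
    """Per-template Chebyshev match counts (self-matches included).

    Returns (a, b): joint (m+1)-point and past m-point counts for templates
    ending at indices m .. N-1.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if HAVE_NUMBA:
        return _entropy_counts_nb(x, m, float(r))
    return _entropy_counts_np(x, m, float(r))


# ---------------------------------------------------------------------------
# FNN neighbor search + criteria counting
#
# For embedding dimension d and delay tau, points are y_i = (x[i], x[i+tau],
# ..., x[i+(d-1)tau]) for i = 0 .. npts-1 with npts = N - d*tau (one extra
# coordinate is reserved so x[i + d*tau] exists for both criteria). The
# nearest neighbor minimizes the Euclidean distance subject to the Theiler
# exclusion |i - j| > w; ties are broken toward the smallest index.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fnn_dim_nb(x, tau, d, theiler, thr_a, thr_b, sigma):  # pragma: no cover
    n = x.shape[0]
    npts = n - d * tau
    c1 = 0
    c2 = 0
    cboth = 0
    zero_denom = 0
    valid = 0
    for i in range(npts):
        best = np.inf
        bj = -1
        for j in range(npts):
            dij = i - j
            if dij < 0:
                dij = -dij
            if dij <= theiler:
                continue
            s = 0.0
            for k in range(d):
                diff = x[i + k * tau] - x[j + k * tau]
                s += diff * diff
                if s >= best:
                    break
            if s < best:
                best = s
                bj = j
        if bj < 0:
            continue
        valid += 1
        dist = np.sqrt(best)
        extra = abs(x[i + d * tau] - x[bj + d * tau])
        t1 = False
        if dist > 0.0:
            t1 = extra / dist > thr_a
        else:
            zero_denom += 1
        t2 = np.sqrt(best + extra * extra) / sigma > thr_b
        if t1:
            c1 += 1
        if t2:
            c2 += 1
        if t1 or t2:
            cboth += 1
    return c1, c2, cboth, zero_denom, valid


def _fnn_dim_np(x: np.ndarray, tau: int, d: int, theiler: int,
                thr_a: float, thr_b: float, sigma: float):
    n = len(x)
    npts = n - d * tau
    idx = np.arange(npts)[:, None] + tau * np.arange(d)[None, :]
    emb = x[idx]  # (npts, d)
    nxt = x[np.arange(npts) + d * tau]
    c1 = c2 = cboth = zero_denom = valid = 0
    for i in range(npts):
        d2 = ((emb - emb[i]) ** 2).sum(axis=1)
        lo = max(0, i - theiler)
        hi = min(npts, i + theiler + 1)
        d2[lo:hi] = np.inf
        bj = int(np.argmin(d2))  # argmin takes the first minimum: smallest index
        if not np.isfinite(d2[bj]):
            continue
        valid += 1
        dist = float(np.sqrt(d2[bj]))
        extra = abs(nxt[i] - nxt[bj])
        t1 = False
        if dist > 0.0:
            t1 = extra / dist > thr_a
        else:
            zero_denom += 1
        t2 = float(np.sqrt(d2[bj] + extra * extra)) / sigma > thr_b
        c1 += t1
        c2 += t2
        cboth += t1 or t2
    return c1, c2, cboth, zero_denom, valid


def fnn_dim_counts(x: np.ndarray, tau: int, d: int, theiler: int,
                   thr_a: float, thr_b: float, sigma: float):
    """Raw FNN counts for one embedding dimension.

    Returns (n_test1, n_test2, n_either, n_zero_denominator, n_valid_points).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if HAVE_NUMBA:
        return _fnn_dim_nb(x, int(tau), int(d), int(theiler),
                           float(thr_a), float(thr_b), float(sigma))
    return _fnn_dim_np(x, int(tau), int(d), int(theiler),
                       float(thr_a), float(thr_b), float(sigma))
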
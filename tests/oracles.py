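"""Independent brute-force oracles for the nonlinear measures.

Deliberately naive O(N^2) implementations with explicit loops, kept free of
any code shared with the package so they can serve as independent
cross-checks on small inputs.
"""

import math

import numpy as np


def brute_entropy_family(x, m, r_abs):
    """(apen, sampen, exp_sampen_values) by direct counting.

    Templates end at n = m .. N-1. Chebyshev closeness at tolerance r_abs;
    self-matches included for ApEn/expSampEn, excluded for SampEn.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    ends = range(m, n)
    exp_vals = []
    a_tot = 0
    b_tot = 0
    for i in ends:
        a_i = 0
        b_i = 0
        for j in ends:
            past_close = all(abs(x[i - m + k] - x[j - m + k]) <= r_abs
                             for k in range(m))
            if past_close:
                b_i += 1
                if abs(x[i] - x[j]) <= r_abs:
                    a_i += 1
        exp_vals.append(-math.log(a_i / b_i))
        a_tot += a_i - 1
        b_tot += b_i - 1
    apen = sum(exp_vals) / len(exp_vals)
    sampen = -math.log(a_tot / b_tot) if a_tot > 0 and b_tot > 0 else float("inf")
    return apen, sampen, np.array(exp_vals)


def brute_fnn(x, tau, d, theiler, thr_a, thr_b, sigma):
    """FNN fractions for one dimension by exhaustive neighbor search.

    Euclidean metric, Theiler exclusion |i-j| <= theiler, nearest neighbor
    ties broken toward the smallest index. Returns
    (frac_test1, frac_test2, frac_combined, n_valid).
    """
    x = np.asarray(x, dtype=float)
    npts = len(x) - d * tau
    c1 = c2 = cb = valid = 0
    for i in range(npts):
        best = float("inf")
        bj = -1
        for j in range(npts):
            if abs(i - j) <= theiler:
                continue
            dist2 = 0.0
            for k in range(d):
                diff = x[i + k * tau] - x[j + k * tau]
                dist2 += diff * diff
            if dist2 < best:
                best = dist2
                bj = j
        if bj < 0:
            continue
        valid += 1
        dist = math.sqrt(best)
        extra = abs(x[i + d * tau] - x[bj + d * tau])
        t1 = dist > 0 and extra / dist > thr_a
        t2 = math.sqrt(best + extra * extra) / sigma > thr_b
        c1 += t1
        c2 += t2
        cb += t1 or t2
    return c1 / valid, c2 / valid, cb / valid, valid


def brute_dfa_fluctuation(x, scales):
    """DFA1 fluctuation function via per-window python loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    profile = np.cumsum(x - x.mean())
    out = []
    for scale in scales:
        scale = int(scale)
        k = n // scale
        ssr = 0.0
        windows = [profile[i * scale:(i + 1) * scale] for i in range(k)]
        windows += [profile[n - (i + 1) * scale: n - i * scale] for i in range(k)]
        for w in windows:
            t = np.arange(scale, dtype=float)
            coef = np.polyfit(t, w, 1)
            resid = w - np.polyval(coef, t)
            ssr += float((resid ** 2).sum())
        out.append(math.sqrt(ssr / (2 * k * scale)))
    return np.array(out)
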
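"""Compiled inner loops for the MIC grid search.

Everything here works on *clump* histograms: samples are reduced to runs of
tied values on each axis, and all candidate cut points sit on clump
boundaries, so tied values never split across bins. Counts are int64; scores
are accumulated in "n * MI" units using a precomputed log table
(``logt[c] = ln c``, ``logt[0] = 0`` so that ``0 * log 0 == 0``).

The dynamic programme in :func:`_dp_fill` is exact: given a fixed partition of
one axis into groups, it maximises the empirical mutual information over all
contiguous partitions of the other axis into at most ``kb`` bins. The
``_enum2_best`` / ``_enum3_best`` drivers wrap it with an exhaustive sweep of
all 2-group (resp. 3-group) cut placements on the fixed axis, which makes the
combined search exact for those grid families.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _dp_fill(val, c, kb, dprev, dcur):
    """Best full-coverage partition score over at most ``kb`` contiguous bins.

    ``val[i, j]`` is the score of a bin covering clumps ``[i, j)``; the score
    of a partition is the sum over its bins. Returns the maximum over 1..kb
    bins of partitions covering all ``c`` clumps.
    """
    for j in range(1, c + 1):
        dprev[j] = val[0, j]
    best = dprev[c]
    tmax = kb if kb < c else c
    for t in range(2, tmax + 1):
        for j in range(t, c + 1):
            m = -1e300
            for i in range(t - 1, j):
                v = dprev[i] + val[i, j]
                if v > m:
                    m = v
            dcur[j] = m
        if dcur[c] > best:
            best = dcur[c]
        for j in range(t, c + 1):
            dprev[j] = dcur[j]
    return best


@njit(cache=True)
def _fill_val2(g0, tot, logt, val, c):
    # bin score: sum_g count*ln(count) - total*ln(total), two groups
    for i in range(c):
        g0i = g0[i]
        ti = tot[i]
        for j in range(i + 1, c + 1):
            a0 = g0[j] - g0i
            t = tot[j] - ti
            a1 = t - a0
            val[i, j] = a0 * logt[a0] + a1 * logt[a1] - t * logt[t]


@njit(cache=True)
def _enum2_best(G, logt, kb):
    """Exact max MI (nats) over grids: 2 bins on axis A x <= kb bins on axis B.

    ``G[a, j]`` counts samples with A-clump <= a among the first ``j`` B-clumps
    (cumulative over both axes), so row ``s-1`` is the low-group prefix for a
    cut after A-clump ``s-1``.
    """
    dA = G.shape[0]
    c = G.shape[1] - 1
    tot = G[dA - 1]
    n = tot[c]
    nlogn = n * logt[n]
    val = np.empty((c + 1, c + 1))
    dprev = np.empty(c + 1)
    dcur = np.empty(c + 1)
    best = -1e300
    for s in range(1, dA):
        g0 = G[s - 1]
        _fill_val2(g0, tot, logt, val, c)
        dp = _dp_fill(val, c, kb, dprev, dcur)
        c0 = g0[c]
        c1 = n - c0
        v = dp + nlogn - c0 * logt[c0] - c1 * logt[c1]
        if v > best:
            best = v
    return best / n


@njit(cache=True)
def _enum3_best(G, logt, kb):
    """Exact max MI (nats) over grids: 3 bins on axis A x <= kb bins on axis B."""
    dA = G.shape[0]
    c = G.shape[1] - 1
    tot = G[dA - 1]
    n = tot[c]
    nlogn = n * logt[n]
    val = np.empty((c + 1, c + 1))
    dprev = np.empty(c + 1)
    dcur = np.empty(c + 1)
    best = -1e300
    for s1 in range(1, dA - 1):
        g0 = G[s1 - 1]
        for s2 in range(s1 + 1, dA):
            g1 = G[s2 - 1]
            for i in range(c):
                a0i = g0[i]
                a1i = g1[i]
                ti = tot[i]
                for j in range(i + 1, c + 1):
                    a0 = g0[j] - a0i
                    a01 = g1[j] - a1i
                    t = tot[j] - ti
                    a1 = a01 - a0
                    a2 = t - a01
                    val[i, j] = (
                        a0 * logt[a0]
                        + a1 * logt[a1]
                        + a2 * logt[a2]
                        - t * logt[t]
                    )
            dp = _dp_fill(val, c, kb, dprev, dcur)
            c0 = g0[c]
            c1 = g1[c] - c0
            c2 = n - g1[c]
            v = dp + nlogn - c0 * logt[c0] - c1 * logt[c1] - c2 * logt[c2]
            if v > best:
                best = v
    return best / n


@njit(cache=True)
def _group_dp_best(S, logt, kb):
    """Max MI (nats) for a fixed A-axis grouping ``S`` and <= kb B-axis bins.

    ``S[g, j]`` counts samples of A-group ``g`` among the first ``j`` B-clumps.
    Used by the equipartition fallback, where the A-partition is a single
    heuristic placement rather than an enumerated one.
    """
    ka = S.shape[0]
    c = S.shape[1] - 1
    n = 0
    for g in range(ka):
        n += S[g, c]
    nlogn = n * logt[n]
    val = np.empty((c + 1, c + 1))
    dprev = np.empty(c + 1)
    dcur = np.empty(c + 1)
    for i in range(c):
        for j in range(i + 1, c + 1):
            t = 0
            acc = 0.0
            for g in range(ka):
                d = S[g, j] - S[g, i]
                t += d
                acc += d * logt[d]
            val[i, j] = acc - t * logt[t]
    dp = _dp_fill(val, c, kb, dprev, dcur)
    v = dp + nlogn
    for g in range(ka):
        cg = S[g, c]
        v -= cg * logt[cg]
    return v / n
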
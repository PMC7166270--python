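"""Maximal Information Coefficient (MIC) between numeric vectors.

MIC measures the dependence between two variables as the maximum, over all
grids drawn on the scatterplot whose cell count stays within a sample-size
budget ``B(n) = n^0.6``, of the empirical mutual information of the induced
2-D histogram normalised by ``log min(x_bins, y_bins)``. The normalisation
puts the statistic on [0, 1]: 0 for independence-like data, 1 for a noiseless
functional relationship.

Search strategy
---------------
For each grid family (smaller-axis bin count ``ka``), the maximisation over
cut placements is solved exactly whenever affordable: every placement of the
``ka - 1`` cuts on the smaller axis is enumerated, and for each placement the
other axis is partitioned optimally by dynamic programming (the DP is exact
for a fixed opposite-axis partition because the MI objective is additive over
bins). When the enumeration work exceeds a fixed cap — only possible at
sample sizes well beyond the small-sample regime this package targets — the
smaller axis falls back to a rank equipartition (the classic MINE-style
approximation), tried in both axis-role assignments. Cut points are only ever
placed between distinct sorted values, so tied samples never split across
bins. Logs are natural throughout; the MIC ratio is base-invariant.
"""

from __future__ import annotations

import math

import numpy as np

from ._mic_kernels import _enum2_best, _enum3_best, _group_dp_best
from .containers import FeatureTable

__all__ = [
    "grid_bound",
    "max_grid_mutual_information",
    "mic",
    "mic_scores",
    "MicCache",
]

MIN_SAMPLES = 4

# Cap on (number of enumerated placements) x (DP table size). Below the cap the
# grid-family search is exact; above it the equipartition approximation is used.
_WORK_CAP = 4_000_000


def grid_bound(n: int) -> float:
    """Grid-size budget ``B(n) = n^0.6`` for the MIC mesh search.

    Clamped from below at 4 so the 2x2 grid is always admissible (for n < 11
    the raw power would exclude even the coarsest informative grid).
    """
    if n < MIN_SAMPLES:
        raise ValueError(f"MIC needs at least {MIN_SAMPLES} samples, got {n}")
    return max(float(n) ** 0.6, 4.0)


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < MIN_SAMPLES:
        raise ValueError(
            f"MIC needs at least {MIN_SAMPLES} samples, got {x.shape[0]}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite; impute missing values first")
    return x, y


def _log_table(n: int) -> np.ndarray:
    t = np.empty(n + 1)
    t[0] = 0.0  # convention 0*log 0 = 0
    t[1:] = np.log(np.arange(1, n + 1, dtype=np.float64))
    return t


def _joint_clumps(x: np.ndarray, y: np.ndarray):
    """Joint histogram over runs of tied values (clumps) on each axis."""
    ux, xi = np.unique(x, return_inverse=True)
    uy, yi = np.unique(y, return_inverse=True)
    C = np.zeros((ux.size, uy.size), dtype=np.int64)
    np.add.at(C, (xi, yi), 1)
    return C


def _prefix(C: np.ndarray) -> np.ndarray:
    """G[a, j] = number of samples with A-clump <= a among the first j B-clumps."""
    q = np.cumsum(np.cumsum(C, axis=1), axis=0)
    return np.concatenate([np.zeros((C.shape[0], 1), dtype=np.int64), q], axis=1)


def _equip_rows(G: np.ndarray, ka: int) -> np.ndarray:
    """Group prefix rows for a rank equipartition of axis A into <= ka bins."""
    dA = G.shape[0]
    cm = G[:, -1]  # cumulative marginal counts per A-clump
    n = int(cm[-1])
    ends: list[int] = []
    lo = 0
    for g in range(1, ka):
        target = n * g / ka
        hi = int(np.searchsorted(cm, target, side="left")) + 1
        hi = max(hi, lo + 1)
        hi = min(hi, dA - (ka - g))
        if hi <= lo:
            break
        ends.append(hi)
        lo = hi
    ends.append(dA)
    rows = np.empty((len(ends), G.shape[1]), dtype=np.int64)
    prev = np.zeros(G.shape[1], dtype=np.int64)
    for g, hi in enumerate(ends):
        rows[g] = G[hi - 1] - prev
        prev = G[hi - 1]
    return rows


def _family_best(Gx: np.ndarray, Gy: np.ndarray, ka: int, kb: int, logt) -> float:
    """Max MI over grids whose smaller axis has ``ka`` bins, other <= ``kb``.

    Both axis-role assignments are searched; each is exact (full cut-placement
    enumeration) when the work bound allows, else equipartition + DP.
    """
    best = -math.inf
    for G in (Gx, Gy):
        dA = G.shape[0]
        c = G.shape[1] - 1
        if ka == 2:
            work = (dA - 1) * c * c
            if dA >= 2 and work <= _WORK_CAP:
                best = max(best, _enum2_best(G, logt, kb))
                continue
        elif ka == 3:
            work = (dA - 1) * (dA - 2) // 2 * c * c
            if dA >= 3 and work <= _WORK_CAP:
                best = max(best, _enum3_best(G, logt, kb))
                continue
        rows = _equip_rows(G, ka)
        best = max(best, _group_dp_best(rows, logt, kb))
    return best


def mic(x, y) -> float:
    """Maximal Information Coefficient of two equal-length numeric vectors.

    Returns a value in [0, 1]; 0 for a constant input (a degenerate axis
    admits no informative partition). Symmetric in its arguments.
    """
    x, y = _validate_pair(x, y)
    n = x.shape[0]
    C = _joint_clumps(x, y)
    if C.shape[0] < 2 or C.shape[1] < 2:
        return 0.0
    bound = grid_bound(n)
    logt = _log_table(n)
    Gx = _prefix(C)
    Gy = _prefix(C.T)
    best = 0.0
    ka = 2
    while ka * ka <= bound:
        kb = int(bound // ka)
        v = _family_best(Gx, Gy, ka, kb, logt)
        best = max(best, v / math.log(ka))
        ka += 1
    return min(1.0, max(0.0, best))


def max_grid_mutual_information(x, y, x_bins: int, y_bins: int) -> float:
    """Maximum empirical mutual information (nats) on an ``x_bins x y_bins`` mesh.

    Maximises over placements of the ``x_bins - 1`` vertical and ``y_bins - 1``
    horizontal cut points (on boundaries between distinct sorted values). Bins
    beyond the number of distinct values, or cut placements the work cap rules
    out, are handled by the same exact-or-equipartition strategy as
    :func:`mic`; because refining a partition never lowers empirical MI, the
    at-most-``k``-bins DP attains the same maximum. Returns 0 for a degenerate
    (constant) axis.
    """
    if x_bins < 2 or y_bins < 2:
        raise ValueError("each axis needs at least 2 bins")
    x, y = _validate_pair(x, y)
    C = _joint_clumps(x, y)
    if C.shape[0] < 2 or C.shape[1] < 2:
        return 0.0
    logt = _log_table(x.shape[0])
    Gx = _prefix(C)
    Gy = _prefix(C.T)
    if x_bins <= y_bins:
        ka, kb, Ga, Gb = x_bins, y_bins, Gx, Gy
    else:
        ka, kb, Ga, Gb = y_bins, x_bins, Gy, Gx
    dA = Ga.shape[0]
    c = Ga.shape[1] - 1
    ka_eff = min(ka, dA)
    if ka_eff == 2 and (dA - 1) * c * c <= _WORK_CAP:
        v = _enum2_best(Ga, logt, kb)
    elif ka_eff == 3 and (dA - 1) * (dA - 2) // 2 * c * c <= _WORK_CAP:
        v = _enum3_best(Ga, logt, kb)
    else:
        v = max(
            _group_dp_best(_equip_rows(Ga, ka_eff), logt, kb),
            _group_dp_best(_equip_rows(Gb, kb), logt, ka_eff),
        )
    return max(0.0, v)


def mic_scores(table: FeatureTable) -> np.ndarray:
    """Per-feature MIC relevance scores against the table's target.

    Returns an array of length ``n_features`` in the table's column order;
    every entry lies in [0, 1].
    """
    if table.n_features < 1:
        raise ValueError("feature table has no feature columns")
    return np.array(
        [mic(table.column(i), table.target) for i in range(table.n_features)]
    )


class MicCache:
    """Lazily filled, symmetric feature-by-feature MIC matrix.

    Redundancy checks during the elimination phase repeatedly need the MIC
    between pairs of feature columns; each pair is computed once and memoised.
    """

    def __init__(self, table: FeatureTable):
        self._table = table
        self._vals: dict[tuple[int, int], float] = {}

    @property
    def n_features(self) -> int:
        return self._table.n_features

    def pair(self, i: int, j: int) -> float:
        """MIC between feature columns ``i`` and ``j`` (``i != j``)."""
        m = self._table.n_features
        if not (0 <= i < m and 0 <= j < m):
            raise IndexError(f"feature index out of range: ({i}, {j})")
        if i == j:
            raise ValueError("self-MIC of a feature is undefined in the cache")
        key = (i, j) if i < j else (j, i)
        v = self._vals.get(key)
        if v is None:
            v = mic(self._table.column(key[0]), self._table.column(key[1]))
            self._vals[key] = v
        return v

    def __len__(self) -> int:
        return len(self._vals)
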
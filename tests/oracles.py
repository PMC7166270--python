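"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the production implementation: the MIC
oracle enumerates every admissible grid shape and every placement of cut
points between distinct sorted values with itertools, computing mutual
information from an explicitly built contingency table; the blanket checker
re-tests the approximate-Markov-blanket definition over all ordered pairs.
"""

import itertools
import math

import numpy as np


def mi_exhaustive_shape(x, y, x_bins, y_bins):
    """Max empirical MI (nats) over all exact cut placements for one shape."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    dx = xi.max() + 1
    dy = yi.max() + 1
    best = None
    for cx in itertools.combinations(range(1, dx), x_bins - 1):
        bx = np.digitize(xi, cx)
        for cy in itertools.combinations(range(1, dy), y_bins - 1):
            by = np.digitize(yi, cy)
            tab = np.zeros((x_bins, y_bins))
            np.add.at(tab, (bx, by), 1)
            p = tab / n
            px = p.sum(axis=1, keepdims=True)
            py = p.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = p * np.log(p / (px * py))
            mi = float(np.nansum(terms))
            if best is None or mi > best:
                best = mi
    return best


def mic_exhaustive(x, y):
    """MIC by full enumeration of admissible grids and cut placements."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    dx = len(np.unique(x))
    dy = len(np.unique(y))
    if dx < 2 or dy < 2:
        return 0.0
    bound = max(n ** 0.6, 4.0)
    best = 0.0
    for kx in range(2, int(bound // 2) + 1):
        for ky in range(2, int(bound // kx) + 1):
            if kx - 1 > dx - 1 or ky - 1 > dy - 1:
                continue
            mi = mi_exhaustive_shape(x, y, kx, ky)
            if mi is not None:
                best = max(best, mi / math.log(min(kx, ky)))
    return min(1.0, best)


def blanket_violations(selected, scores, mic_of_pair):
    """All ordered survivor pairs still satisfying the blanket definition.

    ``mic_of_pair(i, j)`` supplies the feature-feature MIC. A pair (i, j) is a
    violation when i ranks no lower than j (higher score, or equal score with
    the earlier rank position) and both blanket inequalities hold.
    """
    selected = list(selected)
    out = []
    for a, i in enumerate(selected):
        for b, j in enumerate(selected):
            if a == b:
                continue
            ranked_no_lower = scores[i] > scores[j] or (scores[i] == scores[j] and a < b)
            if not ranked_no_lower:
                continue
            if scores[i] >= scores[j] and mic_of_pair(i, j) >= scores[j]:
                out.append((i, j))
    return out
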
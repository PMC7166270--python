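"""Two-phase feature selection: retention-ratio scan + iterative AMB elimination.

Phase 1 ranks all features by MIC relevance to the target, then scans a grid
of retention ratios P, keeping the top ``floor(P * m)`` features at each and
choosing the P whose subset minimises the mean-RMSE objective (ties go to the
larger P, i.e. keep more features).

Phase 2 sorts the candidate subset ascending by score, splits it into K
near-equal contiguous groups, and sweeps them from least to most relevant:
survivors so far are merged with the next group and redundant features are
removed with the approximate-Markov-blanket (AMB) test — feature i blankets
feature j when i is at least as target-relevant as j and MIC(i, j) >=
MIC(j, target). K is chosen from a scan (default 1..15) by the same RMSE
objective (ties go to the smaller K). Survivors are finally labelled strongly
correlated (MIC with the target strictly above the threshold, default 0.6) or
weakly correlated non-redundant.

The end-to-end pipeline is exposed both as the scikit-learn compatible
:class:`CIAMBSelector` transformer and as the :func:`run_ci_amb` convenience
wrapper over it.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import CandidateSubset, FeatureTable, Partition, SelectionResult
from .evaluation import EvalProtocol, make_subset_evaluator
from .mic import MicCache, mic_scores

__all__ = [
    "default_p_grid",
    "default_k_range",
    "retention_count",
    "scan_retention_ratios",
    "partition_ascending",
    "is_approx_markov_blanket",
    "amb_filter",
    "iterative_amb",
    "scan_k",
    "classify_strength",
    "run_ci_amb",
    "CIAMBSelector",
]

STRONG_THRESHOLD = 0.6


def default_p_grid() -> list[float]:
    """Retention-ratio grid 0.95 down to 0.10 in steps of 0.05."""
    return [round(0.95 - 0.05 * i, 2) for i in range(18)]


def default_k_range() -> range:
    """Partition counts 1..15 scanned in phase 2."""
    return range(1, 16)


def retention_count(m: int, p: float) -> int:
    """Number of features kept at retention ratio ``p``: ``floor(p * m)``, min 1."""
    if m < 1:
        raise ValueError("feature count must be >= 1")
    if not (0.0 < p <= 1.0):
        raise ValueError(f"retention ratio must lie in (0, 1], got {p}")
    return max(1, math.floor(p * m))


def _order_desc(scores: np.ndarray, tie_key: np.ndarray | None) -> np.ndarray:
    """Column indices sorted by descending score; ties broken by ``tie_key``."""
    key = np.arange(scores.size) if tie_key is None else tie_key
    return np.lexsort((key, -scores))


def scan_retention_ratios(
    table: FeatureTable,
    scores: np.ndarray,
    p_grid: Sequence[float],
    evaluator: Callable[[np.ndarray], float],
    tie_key: np.ndarray | None = None,
) -> tuple[CandidateSubset, list[tuple[float, float]]]:
    """Choose the retention ratio whose top-scoring subset minimises the objective.

    Returns the winning :class:`CandidateSubset` and the full ``(P, value)``
    trace. Ties between ratios keep the larger P (retain more features).
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("p_grid must be non-empty")
    for p in p_grid:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"retention ratio must lie in (0, 1], got {p}")
    scores = np.asarray(scores, dtype=np.float64)
    m = table.n_features
    if scores.size != m:
        raise ValueError("scores length must match the feature count")
    order = _order_desc(scores, tie_key)
    trace: list[tuple[float, float]] = []
    best_p, best_val, best_idx = None, math.inf, None
    for p in sorted(set(p_grid), reverse=True):
        idx = order[: retention_count(m, p)]
        try:
            val = float(evaluator(idx))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at retention ratio P={p}") from exc
        trace.append((p, val))
        if val < best_val:  # strict: first (largest) P wins ties
            best_p, best_val, best_idx = p, val, idx
    subset = CandidateSubset(
        feature_indices=best_idx,
        scores=scores[best_idx],
        retention_ratio=best_p,
        m_prime=int(best_idx.size),
    )
    return subset, trace


def partition_ascending(
    candidate: CandidateSubset,
    k: int,
    tie_key: np.ndarray | None = None,
) -> Partition:
    """Split the candidate subset into ``k`` score-ascending contiguous groups.

    Group 1 holds the lowest-scoring features; sizes differ by at most one,
    the first ``m' mod k`` groups taking the extra element.
    """
    m_prime = candidate.m_prime
    if not (1 <= k <= m_prime):
        raise ValueError(f"k must lie in [1, {m_prime}], got {k}")
    idx = candidate.feature_indices
    key = idx if tie_key is None else np.asarray(tie_key)[idx]
    asc = idx[np.lexsort((key, candidate.scores))]
    base, rem = divmod(m_prime, k)
    groups: list[np.ndarray] = []
    start = 0
    for g in range(k):
        size = base + (1 if g < rem else 0)
        groups.append(asc[start : start + size])
        start += size
    return Partition(groups=groups, k=k)


def is_approx_markov_blanket(score_i: float, score_j: float, mic_ij: float) -> bool:
    """True iff feature i approximately blankets feature j (j is redundant).

    Requires both ``MIC(i, target) >= MIC(j, target)`` and
    ``MIC(i, j) >= MIC(j, target)``.
    """
    return score_i >= score_j and mic_ij >= score_j


def amb_filter(
    indices: Iterable[int],
    scores: np.ndarray,
    cache: MicCache,
    tie_key: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy AMB sweep: drop every feature blanketed by a surviving better one.

    Features are processed in descending relevance order (so the first blanket
    inequality holds by construction); each survivor eliminates every
    still-unprocessed lower-ranked feature whose target relevance its pairwise
    MIC reaches. Returns the survivors in descending score order.
    """
    idx = np.asarray(list(indices), dtype=np.intp)
    if idx.size == 0:
        return idx
    key = idx if tie_key is None else np.asarray(tie_key)[idx]
    idx = idx[np.lexsort((key, -scores[idx]))]
    removed = np.zeros(idx.size, dtype=bool)
    for a in range(idx.size):
        if removed[a]:
            continue
        i = idx[a]
        for b in range(a + 1, idx.size):
            if removed[b]:
                continue
            j = idx[b]
            if cache.pair(i, j) >= scores[j]:
                removed[b] = True
    return idx[~removed]


def iterative_amb(
    partition: Partition,
    scores: np.ndarray,
    cache: MicCache,
    tie_key: np.ndarray | None = None,
) -> np.ndarray:
    """Iterative K-group AMB elimination.

    The running optimal set starts from the least-relevant group and is
    re-filtered after merging each subsequent group, so highly relevant
    features are merged last, against an already-thinned survivor set. With
    K=1 this is a single plain AMB pass over the whole candidate set.
    """
    t_best = np.empty(0, dtype=np.intp)
    for group in partition.groups:
        merged = np.concatenate([t_best, group])
        t_best = amb_filter(merged, scores, cache, tie_key)
    return t_best


def scan_k(
    candidate: CandidateSubset,
    k_range: Iterable[int],
    scores: np.ndarray,
    cache: MicCache,
    evaluator: Callable[[np.ndarray], float],
    tie_key: np.ndarray | None = None,
) -> tuple[int, np.ndarray, list[tuple[int, float]]]:
    """Choose the partition count K whose post-AMB subset minimises the objective.

    Returns ``(best_k, selected_indices, trace)``; ties keep the smaller K.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if ks[0] < 1 or ks[-1] > candidate.m_prime:
        raise ValueError(
            f"k_range must lie within [1, {candidate.m_prime}], got {ks[0]}..{ks[-1]}"
        )
    trace: list[tuple[int, float]] = []
    best_k, best_val, best_sel = None, math.inf, None
    for k in ks:
        sel = iterative_amb(partition_ascending(candidate, k, tie_key), scores, cache, tie_key)
        try:
            val = float(evaluator(sel))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at K={k}") from exc
        trace.append((k, val))
        if val < best_val:  # strict: first (smallest) K wins ties
            best_k, best_val, best_sel = k, val, sel
    return best_k, best_sel, trace


def classify_strength(
    selected: Sequence[int],
    scores: np.ndarray,
    threshold: float = STRONG_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Split survivors at the strong-correlation threshold (strictly greater)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    selected = np.asarray(selected, dtype=np.intp)
    mask = scores[selected] > threshold if selected.size else np.empty(0, dtype=bool)
    return selected[mask], selected[~mask]


class CIAMBSelector(SelectorMixin, BaseEstimator):
    """Two-phase MIC / iterative-AMB feature selector.

    Parameters
    ----------
    p_grid : sequence of float in (0, 1], optional
        Retention ratios scanned in phase 1. Default 0.95..0.10, step 0.05.
    k_range : iterable of int, optional
        Partition counts scanned in phase 2; values above the candidate size
        are dropped. Default 1..15.
    threshold : float, default 0.6
        Strong/weak split on the survivors' MIC scores (strictly greater is
        strong).
    evaluator : None, EvalProtocol, or callable
        Objective for both scans. ``None`` uses the default protocol (6:4
        split, 10 repeats, mean RMSE of GBDT + XGBoost seeded from
        ``random_state``). An :class:`~ciamb.evaluation.EvalProtocol`
        customises that harness; a callable ``f(table, indices) -> float`` is
        used directly (handy for fast surrogates in tests).
    tie_break : {"column", "name"}, default "column"
        Tie-break for equal MIC scores: original column order, or canonical
        (sorted) feature-name order, which makes the selected set invariant
        to column permutations.
    random_state : int, default 0
        Seeds the evaluation splits and regressors.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        MIC of every feature with the target.
    support_ : bool ndarray of shape (n_features,)
        Mask of the selected features.
    selected_indices_, strong_indices_, weak_indices_ : ndarray
        Final subset (descending score) and its strong/weak split.
    retention_ratio_, n_partitions_ : float, int
        The chosen P and K.
    p_scan_trace_, k_scan_trace_ : list of tuple
        (P, mean RMSE) and (K, mean RMSE) scan traces.
    result_ : SelectionResult
        The full structured result.
    """

    def __init__(
        self,
        p_grid=None,
        k_range=None,
        threshold: float = STRONG_THRESHOLD,
        evaluator=None,
        tie_break: str = "column",
        random_state: int = 0,
    ):
        self.p_grid = p_grid
        self.k_range = k_range
        self.threshold = threshold
        self.evaluator = evaluator
        self.tie_break = tie_break
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X, y):
        """Run both phases on ``(X, y)`` and record the selection."""
        X, y = validate_data(self, X, y, ensure_min_samples=4, y_numeric=True)
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        table = FeatureTable(X, list(names), y)
        self.result_ = self._fit_table(table)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.selected_indices] = True
        return mask

    # -- the actual pipeline ------------------------------------------------
    def _tie_key(self, table: FeatureTable) -> np.ndarray | None:
        if self.tie_break == "column":
            return None
        if self.tie_break == "name":
            return np.argsort(np.argsort(np.asarray(table.feature_names)))
        raise ValueError(f"tie_break must be 'column' or 'name', got {self.tie_break!r}")

    def _make_evaluator(self, table: FeatureTable) -> Callable[[np.ndarray], float]:
        ev = self.evaluator
        if ev is None:
            ev = EvalProtocol(seed=self.random_state)
        if isinstance(ev, EvalProtocol):
            return make_subset_evaluator(table, ev)
        if callable(ev):
            return lambda idx: float(ev(table, idx))
        raise ValueError("evaluator must be None, an EvalProtocol, or a callable")

    def _fit_table(self, table: FeatureTable) -> SelectionResult:
        """Run the pipeline on a prebuilt :class:`FeatureTable`."""
        tie_key = self._tie_key(table)
        evaluator = self._make_evaluator(table)
        scores = mic_scores(table)
        cache = MicCache(table)
        p_grid = default_p_grid() if self.p_grid is None else self.p_grid
        candidate, p_trace = scan_retention_ratios(
            table, scores, p_grid, evaluator, tie_key
        )
        k_range = default_k_range() if self.k_range is None else self.k_range
        ks = [k for k in k_range if 1 <= k <= candidate.m_prime]
        if not ks:
            ks = [1]
        best_k, selected, k_trace = scan_k(
            candidate, ks, scores, cache, evaluator, tie_key
        )
        strong, weak = classify_strength(selected, scores, self.threshold)
        self.scores_ = scores
        self.selected_indices_ = selected
        self.strong_indices_ = strong
        self.weak_indices_ = weak
        self.retention_ratio_ = candidate.retention_ratio
        self.n_partitions_ = best_k
        self.p_scan_trace_ = p_trace
        self.k_scan_trace_ = k_trace
        self.n_features_in_ = table.n_features
        self.result_ = SelectionResult(
            selected_indices=selected,
            strong_indices=strong,
            weak_indices=weak,
            chosen_P=candidate.retention_ratio,
            chosen_K=best_k,
            p_scan_trace=p_trace,
            k_scan_trace=k_trace,
            m_double_prime=int(selected.size),
        )
        return self.result_


def run_ci_amb(
    table: FeatureTable,
    p_grid=None,
    k_range=None,
    threshold: float = STRONG_THRESHOLD,
    evaluator=None,
    tie_break: str = "column",
    seed: int = 0,
) -> SelectionResult:
    """End-to-end two-phase selection on a :class:`FeatureTable`.

    Thin wrapper over :class:`CIAMBSelector`; see that class for parameter
    semantics. Deterministic for a fixed table, configuration and seed.
    """
    selector = CIAMBSelector(
        p_grid=p_grid,
        k_range=k_range,
        threshold=threshold,
        evaluator=evaluator,
        tie_break=tie_break,
        random_state=seed,
    )
    return selector._fit_table(table)
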
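"""In-memory containers shared across the selection pipeline.

A :class:`FeatureTable` is the package's canonical input: an ``n x m`` numeric
matrix of feature intensities (one column per measured substance, e.g. an m/z
channel from an HPLC/MS run), a continuous response vector (one value per
sample), and unique feature names. All downstream stages assume the table is
complete — missing values must be imputed at ingestion time (see
:mod:`ciamb.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTable",
    "CandidateSubset",
    "Partition",
    "SelectionResult",
]


@dataclass
class FeatureTable:
    """Samples-by-features numeric matrix with a continuous target.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature matrix. Must be finite (impute before constructing).
    feature_names : list of str
        Unique column names, one per feature.
    target : ndarray of shape (n_samples,)
        Continuous response (the regression target).
    target_name : str, default "target"
        Name of the response column.
    """

    values: np.ndarray
    feature_names: list[str]
    target: np.ndarray
    target_name: str = "target"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64).ravel()
        self.feature_names = [str(s) for s in self.feature_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, m = self.values.shape
        if m < 1:
            raise ValueError("feature table needs at least one feature column")
        if n < 4:
            raise ValueError(f"feature table needs at least 4 samples, got {n}")
        if self.target.shape[0] != n:
            raise ValueError(
                f"target length {self.target.shape[0]} does not match {n} samples"
            )
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match the matrix width")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.target)):
            raise ValueError("feature table contains non-finite values; impute first")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i]


@dataclass
class CandidateSubset:
    """Phase-1 survivors: the top-scoring features at the chosen retention ratio.

    ``feature_indices`` is ordered by descending relevance score (ties broken
    deterministically); ``scores`` holds the matching per-feature MIC values.
    """

    feature_indices: np.ndarray
    scores: np.ndarray
    retention_ratio: float
    m_prime: int

    def __post_init__(self) -> None:
        self.feature_indices = np.asarray(self.feature_indices, dtype=np.intp)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.feature_indices.shape != self.scores.shape:
            raise ValueError("indices and scores must align")
        if self.m_prime != self.feature_indices.size:
            raise ValueError("m_prime must equal the number of retained features")
        if not (0.0 < self.retention_ratio <= 1.0):
            raise ValueError("retention ratio must lie in (0, 1]")


@dataclass
class Partition:
    """The candidate subset split into ``k`` score-ascending contiguous groups.

    Group 1 holds the lowest-scoring features; concatenating the groups yields
    the candidate set in ascending score order. Group sizes differ by at most
    one, with the first ``m' mod k`` groups holding the extra element.
    """

    groups: list[np.ndarray]
    k: int

    def __post_init__(self) -> None:
        if self.k != len(self.groups):
            raise ValueError("k must equal the number of groups")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        sizes = [len(g) for g in self.groups]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("group sizes may differ by at most one")


@dataclass
class SelectionResult:
    """Final output of the two-phase selection.

    ``selected_indices`` is the optimal subset (descending relevance order);
    ``strong_indices`` / ``weak_indices`` split it at the strong-correlation
    threshold (strict ``score > threshold``). Traces record the mean RMSE seen
    at every retention ratio P and every partition count K during the scans.
    """

    selected_indices: np.ndarray
    strong_indices: np.ndarray
    weak_indices: np.ndarray
    chosen_P: float
    chosen_K: int
    p_scan_trace: list[tuple[float, float]] = field(default_factory=list)
    k_scan_trace: list[tuple[int, float]] = field(default_factory=list)
    m_double_prime: int = 0

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=np.intp)
        self.strong_indices = np.asarray(self.strong_indices, dtype=np.intp)
        self.weak_indices = np.asarray(self.weak_indices, dtype=np.intp)
        merged = set(self.strong_indices) | set(self.weak_indices)
        if merged != set(self.selected_indices) or (
            set(self.strong_indices) & set(self.weak_indices)
        ):
            raise ValueError("strong and weak lists must partition the selection")
        if self.m_double_prime != self.selected_indices.size:
            raise ValueError("m_double_prime must equal the selection size")
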
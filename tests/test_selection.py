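"""Unit and property tests for the two-phase selection pipeline."""

import numpy as np
import pytest

from ciamb import (
    CandidateSubset,
    CIAMBSelector,
    FeatureTable,
    MicCache,
    amb_filter,
    classify_strength,
    default_p_grid,
    is_approx_markov_blanket,
    iterative_amb,
    partition_ascending,
    retention_count,
    run_ci_amb,
    scan_k,
    scan_retention_ratios,
)
from ciamb.mic import mic_scores
from ciamb.synthetic import ScenarioSpec, generate
from conftest import fast_protocol
from oracles import blanket_violations


class TestRetentionCount:
    @pytest.mark.parametrize(
        "m,p,expected",
        [(798, 0.85, 678), (127, 0.95, 120), (103, 0.7, 72), (10, 1.0, 10)],
    )
    def test_floor_convention(self, m, p, expected):
        assert retention_count(m, p) == expected

    def test_never_below_one(self):
        assert retention_count(5, 0.01) == 1

    @pytest.mark.parametrize("p", [0.0, -0.2, 1.5])
    def test_out_of_range_ratio_rejected(self, p):
        with pytest.raises(ValueError):
            retention_count(100, p)


class TestScanRetentionRatios:
    def test_default_grid_runs_095_down_to_010(self):
        grid = default_p_grid()
        assert grid[0] == 0.95 and grid[-1] == 0.10
        assert len(grid) == 18
        steps = {round(a - b, 10) for a, b in zip(grid, grid[1:])}
        assert steps == {0.05}

    def test_argmin_over_mocked_evaluator(self, small_table):
        scores = np.linspace(1, 0, 12)
        # subset sizes at P = 0.95, 0.5, 0.1 on 12 features: 11, 6, 1
        by_size = {11: 5.0, 6: 1.0, 1: 3.0}

        subset, trace = scan_retention_ratios(
            small_table, scores, [0.95, 0.5, 0.1], lambda idx: by_size[len(idx)]
        )
        assert subset.retention_ratio == 0.5
        assert subset.m_prime == retention_count(12, 0.5)
        assert dict(trace) == {0.95: 5.0, 0.5: 1.0, 0.1: 3.0}

    def test_ties_keep_more_features(self, small_table):
        scores = np.linspace(1, 0, 12)
        subset, _ = scan_retention_ratios(
            small_table, scores, [0.9, 0.4], lambda idx: 1.0
        )
        assert subset.retention_ratio == 0.9

    def test_top_features_by_descending_score(self, small_table):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=12)
        subset, _ = scan_retention_ratios(small_table, scores, [0.5], lambda idx: 0.0)
        expected = np.argsort(-scores)[:6]
        assert np.array_equal(subset.feature_indices, expected)

    def test_single_full_ratio_keeps_everything(self, small_table):
        calls = []
        subset, _ = scan_retention_ratios(
            small_table,
            np.linspace(1, 0, 12),
            [1.0],
            lambda idx: calls.append(len(idx)) or 0.0,
        )
        assert subset.m_prime == 12 and calls == [12]

    def test_evaluator_failure_names_the_ratio(self, small_table):
        def bad(idx):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="P=0.5"):
            scan_retention_ratios(small_table, np.linspace(1, 0, 12), [0.5], bad)


def _subset(scores, p=1.0):
    order = np.argsort(-scores)
    k = retention_count(len(scores), p)
    return CandidateSubset(order[:k], scores[order[:k]], p, k)


class TestPartitionAscending:
    def test_sizes_differ_by_at_most_one(self):
        scores = np.random.default_rng(0).uniform(size=678)
        part = partition_ascending(_subset(scores), 5)
        assert [len(g) for g in part.groups] == [136, 136, 136, 135, 135]

    def test_single_group_is_whole_candidate(self):
        scores = np.random.default_rng(1).uniform(size=9)
        cand = _subset(scores)
        part = partition_ascending(cand, 1)
        assert set(part.groups[0]) == set(cand.feature_indices)

    def test_groups_follow_ascending_scores(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        part = partition_ascending(_subset(scores), 3)
        grouped = [list(scores[g]) for g in part.groups]
        assert grouped == [[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]]

    def test_k_beyond_candidate_size_rejected(self):
        scores = np.array([0.3, 0.1])
        with pytest.raises(ValueError):
            partition_ascending(_subset(scores), 3)


class TestBlanketPredicate:
    @pytest.mark.parametrize(
        "si,sj,mij,expected",
        [
            (0.8, 0.5, 0.6, True),
            (0.4, 0.5, 0.9, False),  # relevance inequality fails
            (0.8, 0.5, 0.4, False),  # dependence inequality fails
            (0.5, 0.5, 0.5, True),  # boundary: both hold with equality
        ],
    )
    def test_truth_table(self, si, sj, mij, expected):
        assert is_approx_markov_blanket(si, sj, mij) is expected


def _planted_table(seed=0, n=50):
    """Small table with two exact duplicate pairs and independent columns."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n, 6))
    X = np.column_stack([base, base[:, 0], base[:, 1]])  # cols 6,7 duplicate 0,1
    y = base[:, 0] + 0.6 * base[:, 1] + 0.3 * rng.standard_normal(n)
    names = [f"v{i}" for i in range(8)]
    return FeatureTable(X, names, y)


class TestAmbFilter:
    def test_exact_duplicate_collapses(self):
        table = _planted_table()
        scores = mic_scores(table)
        cache = MicCache(table)
        survivors = amb_filter([0, 6], scores, cache)
        assert len(survivors) == 1

    def test_singleton_survives(self):
        table = _planted_table()
        survivors = amb_filter([3], mic_scores(table), MicCache(table))
        assert list(survivors) == [3]

    def test_empty_input_empty_output(self):
        table = _planted_table()
        assert amb_filter([], mic_scores(table), MicCache(table)).size == 0

    def test_survivors_blanket_free_by_bruteforce(self):
        table = _planted_table(seed=5)
        scores = mic_scores(table)
        cache = MicCache(table)
        survivors = amb_filter(range(8), scores, cache)
        assert blanket_violations(list(survivors), scores, cache.pair) == []

    def test_survivors_in_descending_score_order(self):
        table = _planted_table(seed=2)
        scores = mic_scores(table)
        survivors = amb_filter(range(8), scores, MicCache(table))
        assert np.all(np.diff(scores[survivors]) <= 0)


class TestIterativeAmb:
    def test_single_group_equals_plain_filter(self):
        table = _planted_table(seed=3)
        scores = mic_scores(table)
        cache = MicCache(table)
        cand = _subset(scores)
        merged = iterative_amb(partition_ascending(cand, 1), scores, cache)
        direct = amb_filter(cand.feature_indices, scores, cache)
        assert np.array_equal(merged, direct)

    def test_non_blanketing_features_all_survive(self):
        # orthogonal binary patterns: every pairwise MIC is 0, scores can't blanket
        n = 32
        X = np.column_stack(
            [np.tile(np.repeat([0.0, 1.0], 2 ** i), n // 2 ** (i + 1)) for i in range(3)]
        )
        rng = np.random.default_rng(0)
        y = rng.standard_normal(n)
        table = FeatureTable(X, ["a", "b", "c"], y)
        scores = mic_scores(table)
        cache = MicCache(table)
        for k in (1, 2, 3):
            out = iterative_amb(
                partition_ascending(_subset(scores), k), scores, cache
            )
            assert set(out) == {0, 1, 2}

    def test_planted_copies_never_cosurvive(self):
        table = _planted_table(seed=7)
        scores = mic_scores(table)
        cache = MicCache(table)
        out = iterative_amb(partition_ascending(_subset(scores), 3), scores, cache)
        out = set(out)
        assert not ({0, 6} <= out) and not ({1, 7} <= out)
        assert blanket_violations(sorted(out), scores, cache.pair) == []


class TestScanK:
    def test_ties_keep_smallest_k(self):
        table = _planted_table()
        scores = mic_scores(table)
        cache = MicCache(table)
        k, _, _ = scan_k(
            _subset(scores), range(1, 7), scores, cache, lambda idx: 0.0
        )
        assert k == 1

    def test_mocked_minimum_is_respected(self):
        table = _planted_table()
        scores = mic_scores(table)
        cache = MicCache(table)
        cand = _subset(scores)
        vals = iter([3.0, 1.0, 2.0])
        k, _, trace = scan_k(cand, [1, 2, 3], scores, cache, lambda idx: next(vals))
        assert k == 2
        assert [t[0] for t in trace] == [1, 2, 3]

    def test_out_of_range_k_rejected(self):
        table = _planted_table()
        scores = mic_scores(table)
        cand = _subset(scores)
        with pytest.raises(ValueError):
            scan_k(cand, [0, 5], scores, MicCache(table), lambda idx: 0.0)


class TestClassifyStrength:
    def test_strictly_greater_than_threshold(self):
        scores = np.array([0.61, 0.60, 0.10])
        strong, weak = classify_strength([0, 1, 2], scores, 0.6)
        assert list(strong) == [0]
        assert list(weak) == [1, 2]

    def test_empty_selection(self):
        strong, weak = classify_strength([], np.array([]), 0.6)
        assert strong.size == 0 and weak.size == 0

    def test_all_perfect_scores_are_strong(self):
        strong, weak = classify_strength([0, 1], np.ones(2), 0.6)
        assert list(strong) == [0, 1] and weak.size == 0


class TestEndToEnd:
    def test_single_feature_table_selects_it(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        table = FeatureTable(y.reshape(-1, 1) * 2.0, ["only"], y)
        res = run_ci_amb(table, evaluator=fast_protocol(0), seed=0)
        assert list(res.selected_indices) == [0]
        assert res.m_double_prime == 1

    def test_anti_monotone_counts(self, default_study):
        for run in default_study:
            res = run["result"]
            m = run["table"].n_features
            m_prime = retention_count(m, res.chosen_P)
            assert res.m_double_prime <= m_prime <= m

    def test_same_seed_reproduces_result(self):
        table, _ = generate(ScenarioSpec(seed=4, n_noise=10))
        a = run_ci_amb(table, evaluator=fast_protocol(1), seed=1)
        b = run_ci_amb(table, evaluator=fast_protocol(1), seed=1)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.p_scan_trace == b.p_scan_trace
        assert a.k_scan_trace == b.k_scan_trace

    def test_column_permutation_invariance_with_name_tiebreak(self):
        table, _ = generate(ScenarioSpec(seed=9, n_noise=10))
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_features)
        shuffled = FeatureTable(
            table.values[:, perm],
            [table.feature_names[j] for j in perm],
            table.target,
        )
        res_a = run_ci_amb(
            table, evaluator=fast_protocol(2), tie_break="name", seed=2
        )
        res_b = run_ci_amb(
            shuffled, evaluator=fast_protocol(2), tie_break="name", seed=2
        )
        names_a = {table.feature_names[i] for i in res_a.selected_indices}
        names_b = {shuffled.feature_names[i] for i in res_b.selected_indices}
        assert names_a == names_b


class TestSklearnInterface:
    def test_fit_transform_selects_columns(self, small_table):
        sel = CIAMBSelector(
            p_grid=[0.5, 0.25],
            k_range=[1, 2],
            evaluator=lambda table, idx: float(len(idx)),
            random_state=0,
        )
        Xt = sel.fit_transform(small_table.values, small_table.target)
        assert Xt.shape[0] == small_table.n_samples
        assert Xt.shape[1] == sel.selected_indices_.size
        assert sel.get_support().sum() == Xt.shape[1]

    def test_get_set_params_roundtrip(self):
        sel = CIAMBSelector(threshold=0.5)
        params = sel.get_params()
        assert params["threshold"] == 0.5
        sel.set_params(threshold=0.7)
        assert sel.threshold == 0.7
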
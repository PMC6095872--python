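"""Consensus clustering: matrices, CDF-area selection, consensus summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from radiomix.consensus import (
    ALGORITHMS,
    DISSIMILARITIES,
    ConsensusRun,
    dissimilarity_matrix,
    median_cluster_consensus,
    run_consensus,
    select_best_algorithm,
    select_num_clusters,
)


def _blobs(n_per=20, n_groups=2, sep=20.0, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for g in range(n_groups):
        center = np.zeros(dim)
        center[g % dim] = sep * g
        parts.append(center + rng.standard_normal((n_per, dim)))
        labels += [g] * n_per
    x = pd.DataFrame(np.vstack(parts))
    x.columns = [f"f{i}" for i in range(dim)]
    return x, np.array(labels)


def _toy_run(consensus_by_k, labels_by_k, areas=None):
    ks = tuple(consensus_by_k)
    run = ConsensusRun(
        algorithm="HC_ward",
        dissimilarity="euclidean",
        k_range=ks,
        n_iter=1,
        subsample_frac=1.0,
        seed=0,
        item_ids=[],
        consensus=consensus_by_k,
        labels=labels_by_k,
    )
    if areas:
        run.cdf_area.update(areas)
        ks_sorted = sorted(areas)
        for i, k in enumerate(ks_sorted):
            run.delta_area[k] = (
                areas[k]
                if i == 0
                else (areas[k] - areas[ks_sorted[i - 1]]) / areas[ks_sorted[i - 1]]
            )
    return run


class TestRunConsensus:
    def test_two_separated_blobs_high_within_consensus(self):
        x, labels = _blobs()
        run = run_consensus(x, "HC_ward", "euclidean", k_range=(2, 3), n_iter=100, seed=1)
        m = run.consensus[2]
        within = (labels[:, None] == labels[None, :]) & ~np.eye(len(labels), dtype=bool)
        assert m[within].min() >= 0.99
        assert m[~within & ~np.eye(len(labels), dtype=bool)].max() <= 0.01

    def test_seeded_determinism_byte_identical(self):
        x, _ = _blobs(seed=3)
        a = run_consensus(x, "KM", "euclidean", k_range=(2, 3), n_iter=30, seed=5)
        b = run_consensus(x, "KM", "euclidean", k_range=(2, 3), n_iter=30, seed=5)
        for k in (2, 3):
            np.testing.assert_array_equal(a.consensus[k], b.consensus[k])
            np.testing.assert_array_equal(a.labels[k], b.labels[k])
        assert a.cdf_area == b.cdf_area

    def test_single_full_iteration_gives_binary_matrix(self):
        x, _ = _blobs(seed=7)
        run = run_consensus(
            x, "HC_ward", "euclidean", k_range=(2, 3), n_iter=1, subsample_frac=1.0, seed=2
        )
        m = run.consensus[2].copy()
        np.fill_diagonal(m, 0.0)
        assert set(np.unique(m)).issubset({0.0, 1.0})

    def test_consensus_matrix_invariants(self):
        x, _ = _blobs(n_per=12, seed=11)
        for algorithm in ALGORITHMS:
            run = run_consensus(
                x, algorithm, "euclidean", k_range=(2, 4), n_iter=25, seed=4
            )
            for m in run.consensus.values():
                assert m.min() >= 0.0 and m.max() <= 1.0
                np.testing.assert_allclose(m, m.T)
                np.testing.assert_allclose(np.diag(m), 1.0)

    @pytest.mark.parametrize("dissimilarity", DISSIMILARITIES)
    def test_all_dissimilarities_separate_opposite_profiles(self, dissimilarity):
        # groups with mirrored feature profiles separate under distance and
        # under both correlation-based measures
        rng = np.random.default_rng(2)
        profile = np.array([1.0, 2, 3, 4, 5, 6])
        x = pd.DataFrame(
            np.vstack(
                [profile + 0.3 * rng.standard_normal((10, 6)),
                 profile[::-1] + 0.3 * rng.standard_normal((10, 6))]
            ),
            columns=[f"f{i}" for i in range(6)],
        )
        labels = np.repeat([0, 1], 10)
        run = run_consensus(x, "PAM", dissimilarity, k_range=(2, 3), n_iter=20, seed=9)
        assert adjusted_rand_score(labels, run.labels[2]) == pytest.approx(1.0)

    def test_dissimilarity_guard_constant_rows(self):
        x = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) * 2])
        d = dissimilarity_matrix(x, "one_minus_pearson")
        assert d[0, 1] == pytest.approx(1.0)  # constant row: correlation taken as 0
        assert d[1, 2] == pytest.approx(0.0)


class TestSelection:
    def test_stated_area_arithmetic(self):
        run = _toy_run(
            {k: np.eye(3) for k in (2, 3, 4)},
            {k: np.zeros(3, int) for k in (2, 3, 4)},
            areas={2: 0.5, 3: 0.9, 4: 0.92},
        )
        assert select_num_clusters(run) == 3

    def test_tie_breaks_toward_smaller_k(self):
        run = _toy_run(
            {k: np.eye(3) for k in (2, 3)},
            {k: np.zeros(3, int) for k in (2, 3)},
            areas={2: 0.5, 3: 1.0},
        )
        # delta(2) = 0.5 and delta(3) = 1.0: pick 3; equal deltas pick smaller
        assert select_num_clusters(run) == 3
        run.delta_area[3] = run.delta_area[2]
        assert select_num_clusters(run) == 2

    def test_three_planted_blobs_recover_k3(self):
        x, labels = _blobs(n_per=15, n_groups=3, sep=25.0, seed=13)
        run = run_consensus(x, "HC_ward", "euclidean", k_range=(2, 3, 4, 5), n_iter=100, seed=3)
        k = select_num_clusters(run)
        assert k == 3
        assert adjusted_rand_score(labels, run.labels[3]) >= 0.95

    def test_requires_k_span(self):
        run = _toy_run({2: np.eye(3)}, {2: np.zeros(3, int)}, areas={2: 0.4})
        with pytest.raises(ValueError):
            select_num_clusters(run)


class TestClusterConsensus:
    def test_perfect_blobs_median_cc_one(self):
        x, _ = _blobs(seed=21)
        run = run_consensus(x, "HC_ward", "euclidean", k_range=(2, 3), n_iter=40, seed=6)
        assert median_cluster_consensus(run, 2) == pytest.approx(1.0)

    def test_constant_matrix_returns_constant(self):
        n = 9
        m = np.full((n, n), 0.6)
        np.fill_diagonal(m, 1.0)
        run = _toy_run({3: m}, {3: np.repeat([0, 1, 2], 3)})
        assert median_cluster_consensus(run, 3) == pytest.approx(0.6)

    def test_hand_built_three_cluster_median(self):
        # per-cluster mean consensus 0.9, 0.7, 0.8 -> median 0.8
        n = 6
        m = np.eye(n)
        labels = np.repeat([0, 1, 2], 2)
        for pair, c in (((0, 1), 0.9), ((2, 3), 0.7), ((4, 5), 0.8)):
            m[pair[0], pair[1]] = m[pair[1], pair[0]] = c
        run = _toy_run({3: m}, {3: labels})
        assert median_cluster_consensus(run, 3) == pytest.approx(0.8)

    def test_singleton_cluster_counts_as_one(self):
        m = np.eye(3)
        run = _toy_run({2: m}, {2: np.array([0, 0, 1])})
        vals = median_cluster_consensus(run, 2)
        assert 0.0 <= vals <= 1.0


class TestBestAlgorithm:
    def test_perfect_labels_win_with_v_one(self):
        rng = np.random.default_rng(0)
        outcome = np.repeat([0, 1], 25)
        perfect = outcome.copy()
        noise = rng.integers(0, 2, 50)
        run, v = select_best_algorithm(["noisy", "exact"], [noise, perfect], outcome)
        assert run == "exact"
        assert v == pytest.approx(1.0)

    def test_tie_returns_first_run(self):
        outcome = np.repeat([0, 1], 20)
        labels = outcome.copy()
        run, _ = select_best_algorithm(["a", "b"], [labels, labels], outcome)
        assert run == "a"

    def test_constructed_tables_pick_higher_v(self):
        # labels agreeing 70/50 vs 55/50 with the outcome: V = 0.4 vs 0.1005
        outcome = np.repeat([0, 1], 50)
        strong = np.concatenate([np.zeros(35), np.ones(15), np.zeros(15), np.ones(35)])
        weak = np.concatenate([np.zeros(30), np.ones(20), np.zeros(25), np.ones(25)])
        run, v = select_best_algorithm(["strong", "weak"], [strong, weak], outcome)
        assert run == "strong"
        assert v == pytest.approx(0.4)

    def test_single_level_outcome_rejected(self):
        with pytest.raises(ValueError):
            select_best_algorithm(["a"], [np.array([0, 1, 0, 1])], np.zeros(4))
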
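from itertools import permutations

import numpy as np
import pytest

from simfuse.cluster_analysis import ClusterAssignment, cut_tree, hierarchical_cluster
from simfuse.eta_tuning import amd, disagreement, dunn_index, loo_subsets, tune_eta
from simfuse.fusion_core import FusionConfig


def assignment(labels, k, ids=None):
    labels = np.asarray(labels)
    ids = ids or [f"c{i}" for i in range(labels.size)]
    return ClusterAssignment(ids, labels, k)


def brute_force_disagreement(a, b):
    """Exhaustive minimum over label permutations of b (k <= 6)."""
    pos_b = {c: i for i, c in enumerate(b.compound_ids)}
    common = [(i, pos_b[c]) for i, c in enumerate(a.compound_ids) if c in pos_b]
    best = len(common)
    for perm in permutations(range(1, b.k + 1)):
        relab = {old: new for old, new in zip(range(1, b.k + 1), perm)}
        best = min(
            best,
            sum(1 for ia, ib in common if a.labels[ia] != relab[b.labels[ib]]),
        )
    return best


def brute_force_dunn(D, y):
    n = y.size
    within, between = 0.0, np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if y[i] == y[j]:
                within = max(within, D[i, j])
            else:
                between = min(between, D[i, j])
    return between / within


class TestLooSubsets:
    def test_three_compounds(self):
        subs = loo_subsets(["a", "b", "c"])
        assert [s.tolist() for s in subs] == [[1, 2], [0, 2], [0, 1]]

    def test_count_and_size(self):
        subs = loo_subsets([f"c{i}" for i in range(37)])
        assert len(subs) == 37
        assert all(len(s) == 36 for s in subs)

    def test_pairwise_distinct(self):
        subs = loo_subsets([f"c{i}" for i in range(6)])
        assert len({tuple(s) for s in subs}) == 6

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            loo_subsets(["a", "b"])


class TestDisagreement:
    def test_identical_assignments(self):
        a = assignment([1, 1, 2, 2], 2)
        assert disagreement(a, a) == 0

    def test_relabeling_invariance(self):
        a = assignment([1, 1, 2, 2], 2)
        b = assignment([2, 2, 1, 1], 2)
        assert disagreement(a, b) == 0

    def test_crossed_labels(self):
        a = assignment([1, 1, 2, 2], 2)
        b = assignment([1, 2, 1, 2], 2)
        assert disagreement(a, b) == 2

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="class counts"):
            disagreement(assignment([1, 2], 2), assignment([1, 3], 3))

    def test_restricts_to_common_compounds(self):
        a = assignment([1, 1, 2], 2, ids=["x", "y", "z"])
        b = assignment([1, 2, 2], 2, ids=["y", "z", "w"])
        # common = {y, z}: a gives (1, 2), b gives (1, 2) -> 0
        assert disagreement(a, b) == 0

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_matches_exhaustive_permutation_oracle(self, rng, k):
        for _ in range(10):
            n = int(rng.integers(k, 15))
            a = assignment(rng.integers(1, k + 1, n), k)
            b = assignment(rng.integers(1, k + 1, n), k)
            assert disagreement(a, b) == brute_force_disagreement(a, b)


class TestDunnIndex:
    def test_two_tight_far_pairs(self):
        # within-pair distance 0.1, between-pair 1.0 -> 1.0 / 0.1 = 10
        D = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        assert dunn_index(D, np.array([1, 1, 2, 2])) == pytest.approx(10.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        y = np.array([1, 1, 2, 2, 3, 3])
        swapped = np.array([3, 3, 1, 1, 2, 2])
        assert dunn_index(D, y) == pytest.approx(dunn_index(D, swapped), abs=1e-15)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            D = rng.random((7, 7))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            y = rng.integers(1, 4, 7)
            if len(set(y)) < 2 or (np.bincount(y).max() < 2):
                continue
            assert abs(dunn_index(D, y) - brute_force_dunn(D, y)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dunn_index(np.zeros((3, 3)), np.array([1, 1, 1]))

    def test_all_singletons_returns_inf_with_warning(self):
        D = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.warns(UserWarning, match="unbounded"):
            assert dunn_index(D, np.array([1, 2])) == np.inf


class TestAmd:
    def _trees_from_blocks(self, rng, jitter=0.0):
        """LOO forest over 8 compounds in 2 clean planted blocks."""
        n = 8
        D = np.full((n, n), 0.9)
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    D[i, j] = 0.1
        np.fill_diagonal(D, 0.0)
        if jitter:
            J = rng.uniform(0, jitter, (n, n))
            D = D + (J + J.T) / 2
            np.fill_diagonal(D, 0.0)
        ids = [f"c{i}" for i in range(n)]
        trees = []
        for sub in loo_subsets(ids):
            trees.append(
                hierarchical_cluster(D[np.ix_(sub, sub)], [ids[i] for i in sub])
            )
        return trees

    def test_identical_partitions_give_zero(self, rng):
        trees = self._trees_from_blocks(rng)
        assert amd(trees, (2, 2)) == 0.0

    def test_invariant_to_subset_order(self, rng):
        trees = self._trees_from_blocks(rng, jitter=0.3)
        assert amd(trees, (2, 4)) == amd(trees[::-1], (2, 4))

    def test_k_range_exceeding_subset_rejected(self, rng):
        trees = self._trees_from_blocks(rng)
        with pytest.raises(ValueError):
            amd(trees, (2, 8))

    def test_planted_four_compounds_zero_at_k2(self):
        D = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        ids = ["a", "b", "c", "d"]
        trees = [
            hierarchical_cluster(D[np.ix_(s, s)], [ids[i] for i in s])
            for s in loo_subsets(ids)
        ]
        assert amd(trees, (2, 2)) == 0.0


class TestTuneEta:
    def test_single_point_grid(self, small_views, fast_config):
        vb, vs, _, _ = small_views
        cfg = FusionConfig(eta=1.0, k=3, seed=5, n_restarts=1, max_em=150, max_outer=20)
        rep = tune_eta([vb, vs], [3.0], (2, 5), cfg)
        assert rep.eta_grid.tolist() == [3.0]
        assert rep.recommended_eta == 3.0
        assert rep.n_subsets == 15

    def test_deterministic_given_seed(self, small_views):
        vb, vs, _, _ = small_views
        cfg = FusionConfig(eta=1.0, k=3, seed=5, n_restarts=1, max_em=150, max_outer=20)
        r1 = tune_eta([vb, vs], [0.5, 3.0], (2, 4), cfg)
        r2 = tune_eta([vb, vs], [0.5, 3.0], (2, 4), cfg)
        assert np.array_equal(r1.amd, r2.amd)
        assert np.array_equal(r1.adi_mean, r2.adi_mean)
        assert r1.recommended_eta == r2.recommended_eta

    def test_noiseless_planted_views_are_stable(self):
        from simfuse import (
            PlantedScenario,
            generate_all,
            pearson_similarity,
            tanimoto_similarity,
        )

        sc = PlantedScenario(
            n=9, k_true=3, view_noise=(0.0, 0.0), profile_dim=12, fp_bits=32, seed=2
        )
        profiles, fps, _, _ = generate_all(sc)
        cfg = FusionConfig(eta=1.0, k=3, seed=9, n_restarts=1, max_em=150, max_outer=20)
        rep = tune_eta(
            [pearson_similarity(profiles), tanimoto_similarity(fps)],
            [0.1, 3.0],
            (3, 3),
            cfg,
        )
        # an unambiguous planted structure is stable at the planted k for every eta
        assert np.allclose(rep.amd, 0.0)
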
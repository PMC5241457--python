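"""Day/subject distances, overlap, residuals and membership classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from eigenlife import (EigenBehavior, classify_membership, day_distance_matrix,
                       day_index_vector, group_residual_distance,
                       individual_pair_distances, overlap_percentage)

from conftest import random_behavior_matrix


class TestDayDistances:
    def test_identical_days_distance_zero_and_symmetry(self):
        X = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        d = day_distance_matrix(X, k=1)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_toy_three_day_index_vector(self):
        """Days (a, a, b): the two a-days are mutually nearest; the b-day's
        nearest is day 1 by the smallest-index tie-break."""
        X = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        vec = day_index_vector(day_distance_matrix(X, k=1))
        assert list(vec) == [2, 1, 1]

    def test_all_equal_distances_tie_break(self):
        d = np.ones((4, 4)) - np.eye(4)
        assert list(day_index_vector(d)) == [2, 1, 1, 1]

    def test_two_days(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert list(day_index_vector(d)) == [2, 1]

    def test_full_rank_projection_is_isometric(self, rng):
        """With k = r the weight-vector distances equal the squared
        Euclidean distances between mean-adjusted rows."""
        m = random_behavior_matrix(rng, 7, p=0.4)
        res = EigenBehavior(m).fit()
        d = day_distance_matrix(m, k=res.rank)
        direct = squareform(pdist(m.values, metric="sqeuclidean"))
        assert np.allclose(d, direct, atol=1e-8)

    def test_k_beyond_rank_rejected(self, rng):
        m = random_behavior_matrix(rng, 4)
        with pytest.raises(ValueError):
            day_distance_matrix(m, k=10)


class TestOverlap:
    def test_identical_vectors(self):
        v = np.array([2, 1, 4, 3])
        assert overlap_percentage(v, v) == 1.0

    def test_disjoint_vectors(self):
        assert overlap_percentage(np.array([2, 1]), np.array([1, 2])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage(np.array([1, 2]), np.array([1]))


class TestIndividualDistances:
    def test_self_and_identical_subjects_at_zero(self, rng):
        group = (rng.random((5, 12)) < 0.5).astype(float)
        res = EigenBehavior(group).fit()
        psis = np.vstack([group[0], group[0], group[2]])
        d = individual_pair_distances(res, psis, k=2)
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] > 0

    def test_matches_brute_force_projection(self, rng):
        group = (rng.random((6, 15)) < 0.5).astype(float)
        res = EigenBehavior(group).fit()
        psis = rng.random((4, 15))
        k = 3
        d = individual_pair_distances(res, psis, k=k)
        omegas = np.array([[res.eigvecs[:, i] @ (p - res.psi)
                            for i in range(k)] for p in psis])
        for i in range(4):
            for j in range(4):
                expected = np.sum((omegas[i] - omegas[j]) ** 2)
                assert d[i, j] == pytest.approx(expected, abs=1e-10)


class TestGroupResidual:
    def test_group_mean_has_zero_residual(self, rng):
        group = (rng.random((5, 10)) < 0.5).astype(float)
        res = EigenBehavior(group).fit()
        assert group_residual_distance(res.psi, res, k=2) == pytest.approx(0.0)

    def test_in_subspace_displacement_has_zero_residual(self, rng):
        group = (rng.random((5, 10)) < 0.5).astype(float)
        res = EigenBehavior(group).fit()
        gamma = res.psi + 3.0 * res.eigvecs[:, 0]
        assert group_residual_distance(gamma, res, k=1) == pytest.approx(
            0.0, abs=1e-10)

    def test_orthogonal_displacement_residual_is_norm_squared(self, rng):
        group = (rng.random((5, 10)) < 0.5).astype(float)
        res = EigenBehavior(group).fit()
        v = rng.standard_normal(10)
        v -= res.eigvecs @ (res.eigvecs.T @ v)  # orthogonal complement
        gamma = res.psi + v
        assert group_residual_distance(gamma, res, k=res.rank) == (
            pytest.approx(v @ v, rel=1e-8))

    def test_rank_zero_group_uses_plain_distance(self):
        res = EigenBehavior(np.ones((3, 4))).fit()
        gamma = np.array([1.0, 1.0, 0.0, 1.0])
        assert group_residual_distance(gamma, res) == pytest.approx(1.0)


def separable_psis(rng, n_per=5, H=20):
    """Two groups whose average behaviors lie in disjoint subspaces."""
    base0, base1 = np.zeros(H), np.zeros(H)
    base0[:4] = 0.8
    base1[-4:] = 0.8
    rows, labels = [], []
    for g, base in ((0, base0), (1, base1)):
        for _ in range(n_per):
            noise = rng.normal(0, 0.02, H)
            rows.append(np.clip(base + noise, 0, 1))
            labels.append(g)
    ids = [f"s{i}" for i in range(2 * n_per)]
    psis = pd.DataFrame(rows, index=ids)
    return psis, pd.Series(labels, index=ids)


class TestMembership:
    def test_separable_groups_classified_perfectly(self, rng):
        psis, labels = separable_psis(rng)
        result = classify_membership({"activity": psis}, labels)
        assert result.accuracies["decision_tree"] == 1.0
        assert len(result.feature_names) == 1 * 2  # spaces x groups

    def test_feature_count_is_spaces_times_groups(self, rng):
        psis, labels = separable_psis(rng, n_per=4)
        result = classify_membership({"activity": psis, "diet": psis}, labels)
        assert len(result.feature_names) == 4

    def test_labels_independent_of_behavior_near_chance(self, rng):
        """Random labels give accuracy near the majority-class fraction."""
        psis = pd.DataFrame(rng.random((12, 10)),
                            index=[f"s{i}" for i in range(12)])
        accs = []
        for rep in range(5):
            labels = pd.Series(rng.permutation([0] * 6 + [1] * 6),
                               index=psis.index)
            result = classify_membership({"activity": psis}, labels,
                                         random_state=rep)
            accs.append(result.accuracies["decision_tree"])
        assert 0.2 <= np.mean(accs) <= 0.75

    def test_single_member_group_rejected(self, rng):
        psis = pd.DataFrame(rng.random((4, 6)),
                            index=["a", "b", "c", "d"])
        labels = pd.Series([0, 0, 0, 1], index=psis.index)
        with pytest.raises(ValueError):
            classify_membership({"activity": psis}, labels)
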
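"""Eigenbehavior decomposition, projection and partial-day prediction."""

import numpy as np
import pytest

from eigenlife import EigenBehavior, cv_prediction_accuracy
from eigenlife.behavior import BehaviorMatrix
from eigenlife.lexicons import ACTIVITY

from conftest import random_behavior_matrix


def brute_force_eigen(X):
    """Oracle: dense eigendecomposition of the explicitly formed covariance."""
    C = np.cov(X, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


class TestFit:
    def test_two_antisymmetric_rows(self):
        """Rows (1,0) and (0,1): single eigenbehavior along (1,-1)/sqrt(2)."""
        res = EigenBehavior(np.array([[1.0, 0.0], [0.0, 1.0]])).fit()
        assert res.rank == 1
        assert np.allclose(np.abs(res.eigvecs[:, 0]), 1 / np.sqrt(2))
        assert res.eigvecs[0, 0] > 0  # sign convention
        assert np.allclose(res.evr, [1.0])
        assert np.isclose(res.eigvals[0], 1.0)

    def test_identical_rows_give_rank_zero(self):
        res = EigenBehavior(np.ones((4, 5))).fit()
        assert res.rank == 0
        assert np.allclose(res.psi, 1.0)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            EigenBehavior(np.ones((1, 5)))

    def test_matches_brute_force_covariance_eigendecomposition(self, rng):
        for _ in range(10):
            D = int(rng.integers(3, 15))
            X = (rng.random((D, 20)) < 0.4).astype(float)
            res = EigenBehavior(X).fit()
            vals, vecs = brute_force_eigen(X)
            assert np.allclose(res.eigvals, vals[:res.rank], atol=1e-8)
            for i in range(res.rank):
                dot = abs(res.eigvecs[:, i] @ vecs[:, i])
                assert dot == pytest.approx(1.0, abs=1e-6)

    def test_orthonormality_and_evr_sum(self, rng):
        res = EigenBehavior((rng.random((8, 30)) < 0.3).astype(float)).fit()
        gram = res.eigvecs.T @ res.eigvecs
        assert np.allclose(gram, np.eye(res.rank), atol=1e-10)
        assert res.evr.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(res.eigvals) <= 1e-12).all()
        assert res.rank <= min(7, 30)


class TestPrimaryCount:
    @pytest.mark.parametrize("eigvals, threshold, expected", [
        ([0.95, 0.05], 0.9, 1),
        ([0.5, 0.3, 0.2], 0.9, 3),
        ([0.5, 0.3, 0.2], 1.0, 3),
        ([0.6, 0.3, 0.1], 0.9, 2),
    ])
    def test_cumulative_threshold(self, eigvals, threshold, expected):
        res = EigenBehavior(np.eye(2)).fit()
        res.eigvals = np.asarray(eigvals, dtype=float)
        res.eigvecs = np.zeros((2, len(eigvals)))
        assert res.primary_count(threshold) == expected

    def test_monotone_in_threshold(self, rng):
        res = EigenBehavior((rng.random((10, 27)) < 0.4).astype(float)).fit()
        counts = [res.primary_count(t) for t in (0.5, 0.7, 0.9, 0.99, 1.0)]
        assert counts == sorted(counts)
        assert counts[-1] == res.rank

    def test_rank_zero_rejected(self):
        res = EigenBehavior(np.ones((3, 4))).fit()
        with pytest.raises(ValueError):
            res.primary_count()


class TestProjection:
    def test_psi_projects_to_zero(self, rng):
        res = EigenBehavior((rng.random((6, 12)) < 0.5).astype(float)).fit()
        assert np.allclose(res.project(res.psi), 0.0)

    def test_displacement_along_eigenbehavior(self, rng):
        res = EigenBehavior((rng.random((6, 12)) < 0.5).astype(float)).fit()
        gamma = res.psi + 2.0 * res.eigvecs[:, 0]
        omega = res.project(gamma)
        expected = np.zeros(res.rank)
        expected[0] = 2.0
        assert np.allclose(omega, expected, atol=1e-10)

    def test_matches_explicit_inner_products(self, rng):
        res = EigenBehavior((rng.random((6, 12)) < 0.5).astype(float)).fit()
        gamma = rng.random(12)
        omega = res.project(gamma, k=3)
        manual = [res.eigvecs[:, i] @ (gamma - res.psi) for i in range(3)]
        assert np.allclose(omega, manual)

    def test_zero_weights_reconstruct_psi(self, rng):
        res = EigenBehavior((rng.random((6, 12)) < 0.5).astype(float)).fit()
        assert np.allclose(res.reconstruct(np.zeros(res.rank)), res.psi)

    def test_full_rank_round_trip_on_training_rows(self, rng):
        X = (rng.random((8, 20)) < 0.4).astype(float)
        res = EigenBehavior(X).fit()
        for row in X:
            back = res.reconstruct(res.project(row))
            assert np.allclose(back, row, atol=1e-8)

    def test_reconstruction_error_non_increasing_in_k(self, rng):
        X = (rng.random((9, 25)) < 0.4).astype(float)
        res = EigenBehavior(X).fit()
        gamma = X[0]
        errors = [np.linalg.norm(gamma - res.reconstruct(res.project(gamma, k)))
                  for k in range(res.rank + 1)]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] == pytest.approx(0.0, abs=1e-8)


def alternating_matrix(n_days=6):
    """Deterministic routine alternating between two 4-column day types."""
    a, b = [1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]
    values = np.array([a if d % 2 == 0 else b for d in range(n_days)])
    return values


class TestPartialDayPrediction:
    def test_hand_computed_alternating_example(self):
        """One-eigenbehavior model: observing (1, 0) on the first two
        columns pins omega = 1 and predicts (1, 0) on the last two."""
        res = EigenBehavior(alternating_matrix()).fit()
        assert res.rank == 1
        pred = res.predict_remaining(np.array([1.0, 0.0]),
                                     np.array([0, 1]), np.array([2, 3]), k=1)
        assert np.array_equal(pred, [1.0, 0.0])

    def test_observed_equal_to_psi_gives_thresholded_psi(self, rng):
        X = (rng.random((8, 10)) < 0.4).astype(float)
        res = EigenBehavior(X).fit()
        obs_cols, tgt_cols = np.arange(5), np.arange(5, 10)
        pred = res.predict_remaining(res.psi[obs_cols], obs_cols, tgt_cols,
                                     k=3)
        expected = (res.psi[tgt_cols] >= 0.5).astype(float)
        assert np.array_equal(pred, expected)

    def test_component_count_truncated_to_observed_columns(self, rng):
        X = (rng.random((9, 10)) < 0.5).astype(float)
        res = EigenBehavior(X).fit()
        pred = res.predict_remaining(X[0, :2], np.arange(2), np.arange(2, 10),
                                     k=res.rank)
        assert pred.shape == (8,)
        assert set(pred) <= {0.0, 1.0}

    def test_deterministic_routine_predicts_perfectly(self):
        values = np.zeros((6, 27))
        values[:, :4] = alternating_matrix()
        values[::2, 20] = 1.0  # evening cell tied to the day type
        m = BehaviorMatrix(ACTIVITY, list(range(1, 7)),
                           [f"{c}_P{p}" for c in "abcdefghi" for p in range(3)],
                           values)
        result = cv_prediction_accuracy(m)
        assert result.mean_accuracy == 1.0

    def test_all_zero_targets_are_trivially_predicted(self, rng):
        m = random_behavior_matrix(rng, 6, category=ACTIVITY, p=0.3)
        values = m.values.copy()
        targets = [i for i, c in enumerate(m.col_labels) if c.endswith("_P2")]
        values[:, targets] = 0.0
        m2 = BehaviorMatrix(ACTIVITY, m.row_labels, m.col_labels, values)
        assert cv_prediction_accuracy(m2).mean_accuracy == 1.0

    def test_too_few_days_rejected(self, rng):
        m = random_behavior_matrix(rng, 2)
        with pytest.raises(ValueError):
            cv_prediction_accuracy(m)
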
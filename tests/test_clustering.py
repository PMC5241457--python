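"""Health-indicator clustering, model selection and feature importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from eigenlife import (IndicatorClustering, rank_feature_importance,
                       standardize_indicators)
from eigenlife.clustering import INDICATOR_COLUMNS


def blobs(rng, n_per=4, sep=10.0, n_features=3):
    """Two Gaussian blobs ``sep`` standard deviations apart, centred away
    from the origin so angular (cosine) affinity also separates them."""
    a = rng.standard_normal((n_per, n_features))
    b = rng.standard_normal((n_per, n_features))
    a[:, 0] += sep
    b[:, 1] += sep
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per)]), labels


class TestStandardize:
    def test_zero_variance_column_dropped_with_warning(self, rng):
        table = pd.DataFrame({"a": rng.random(5), "b": np.ones(5)})
        with pytest.warns(UserWarning):
            z = standardize_indicators(table)
        assert list(z.columns) == ["a"]

    def test_columns_centered_and_scaled(self, rng):
        table = pd.DataFrame(rng.random((8, 3)), columns=list("abc"))
        z = standardize_indicators(table)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_symmetric_pair_gets_opposite_scores(self):
        table = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 20.0],
                              "c": [5.0, 6.0]})
        with pytest.raises(ValueError):
            standardize_indicators(table)  # fewer than 3 subjects
        table = pd.DataFrame({"a": [1.0, 3.0, 2.0]})
        z = standardize_indicators(table)
        assert z["a"].iloc[0] == pytest.approx(-z["a"].iloc[1])


class TestSelectClustering:
    def test_well_separated_blobs_recovered_by_both_methods(self, rng):
        """Silhouette-selected configuration on two 10-SD blobs is k=2,
        matches the brute-force best 2-partition, and both methods agree."""
        table, truth = blobs(rng)
        results = IndicatorClustering(table, standardize=False).fit(
            k_range=range(2, 6))
        assert results.k == 2
        assert results.silhouette > 0.8
        assert adjusted_rand_score(truth, results.labels) == 1.0
        # brute-force oracle: best silhouette over all 2-partitions
        X = table.to_numpy()
        best = max(
            (frozenset(c) for r in range(1, 5)
             for c in itertools.combinations(range(8), r)),
            key=lambda c: silhouette_score(
                X, [int(i in c) for i in range(8)]))
        assert best in (frozenset(range(4)), frozenset(range(4, 8)))
        # spectral agrees with k-means on this structure
        spectral = IndicatorClustering(table, standardize=False).fit(
            k_range=[2], methods=("spectral",))
        assert adjusted_rand_score(results.labels, spectral.labels) == 1.0

    def test_structured_k2_beats_overfit_partition_of_noise(self, rng):
        table, _ = blobs(rng)
        structured = IndicatorClustering(table, standardize=False).fit(
            k_range=[2])
        noise = pd.DataFrame(rng.standard_normal((8, 3)),
                             index=table.index)
        overfit = IndicatorClustering(noise, standardize=False).fit(
            k_range=[7])
        assert structured.silhouette > overfit.silhouette

    def test_k_range_validated(self, rng):
        table, _ = blobs(rng)
        with pytest.raises(ValueError):
            IndicatorClustering(table).fit(k_range=[8])

    def test_kmeans_invariant_to_column_permutation(self, rng):
        table, _ = blobs(rng, n_features=5)
        r1 = IndicatorClustering(table, standardize=False).fit(
            k_range=[2], methods=("kmeans",))
        permuted = table[list(table.columns[::-1])]
        r2 = IndicatorClustering(permuted, standardize=False).fit(
            k_range=[2], methods=("kmeans",))
        assert adjusted_rand_score(r1.labels, r2.labels) == 1.0


class TestFeatureImportance:
    def test_thresholded_feature_dominates(self, rng):
        X = rng.standard_normal((40, 11))
        j = 6
        labels = (X[:, j] > np.median(X[:, j])).astype(int)
        imp = rank_feature_importance(X, labels,
                                      feature_names=list(INDICATOR_COLUMNS))
        assert imp.index[0] == INDICATOR_COLUMNS[j]
        assert imp.sum() == pytest.approx(1.0)

    def test_pure_noise_importances_near_uniform(self, rng):
        """With labels independent of features, mean importance over
        repeated fits approaches 1/11 per feature."""
        totals = np.zeros(11)
        n_rep = 20
        for i in range(n_rep):
            X = rng.standard_normal((30, 11))
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                labels[0] = 1 - labels[0]
            totals += rank_feature_importance(
                X, labels, feature_names=list(INDICATOR_COLUMNS),
                random_state=i).reindex(INDICATOR_COLUMNS).to_numpy()
        mean_imp = totals / n_rep
        assert np.allclose(mean_imp, 1 / 11, atol=0.03)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_feature_importance(rng.random((10, 3)), np.zeros(10))


def test_two_group_cohort_recovery(default_cohort):
    """On a synthetic cohort with the default indicator effect size, the
    silhouette-selected configuration is two groups, they match the truth,
    and fitness (vo2max) and basal energy expenditure rank at the top."""
    results = IndicatorClustering(default_cohort.indicators).fit()
    assert results.k == 2
    assert adjusted_rand_score(default_cohort.labels, results.labels) >= 0.9
    assert set(results.importances.index[:2]) == {"vo2max", "bee"}
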
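"""Bodily layer: unsupervised grouping of subjects by health indicators.

Subjects are clustered on 11 numeric health indicators (anthropometrics,
fitness and metabolic measures).  Two methods suited to small cohorts are
compared — k-means and spectral clustering on a cosine-similarity
affinity — over a range of cluster counts, the silhouette score selects
the winning configuration, and an extremely-randomized-trees ensemble
ranks how much each indicator contributes to the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity

INDICATOR_COLUMNS = (
    "age", "bmi", "weight", "height", "vo2max", "rel_vo2max",
    "rmr", "bee", "fat_mass", "fat_free_mass", "pct_fat",
)

METHODS = ("kmeans", "spectral")


def standardize_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each indicator column; zero-variance columns are dropped.

    The indicators mix units of wildly different scale (kcal/day vs kg),
    so unscaled Euclidean clustering would be dominated by the largest
    units.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects to standardize")
    numeric = table.astype(float)
    sd = numeric.std(ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping zero-variance indicators: {list(dead)}")
        numeric = numeric.drop(columns=dead)
        sd = sd.drop(dead)
    return (numeric - numeric.mean()) / sd


def _cluster_labels(X: np.ndarray, method: str, k: int,
                    random_state: int) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        return km.fit_predict(X)
    if method == "spectral":
        # Cosine similarity shifted to [0, 1]: spectral clustering needs a
        # non-negative affinity and z-scored indicators produce negatives.
        affinity = 0.5 * (1.0 + cosine_similarity(X))
        sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                                random_state=random_state)
        return sc.fit_predict(affinity)
    raise ValueError(f"unknown clustering method {method!r}")


def rank_feature_importance(X: np.ndarray, labels: np.ndarray,
                            feature_names: list[str] | None = None,
                            n_trees: int = 101,
                            random_state: int = 0) -> pd.Series:
    """Extra-trees impurity importances of indicators for a grouping.

    101 extremely randomized trees with a fixed seed; importances are
    normalized to sum to 1.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 groups to rank importances")
    forest = ExtraTreesClassifier(n_estimators=n_trees,
                                  random_state=random_state)
    forest.fit(np.asarray(X, dtype=float), labels)
    imp = forest.feature_importances_
    imp = imp / imp.sum()
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(len(imp))]
    return pd.Series(imp, index=feature_names).sort_values(ascending=False)


class IndicatorClustering:
    """Model: find the latent grouping of a cohort by health indicators.

    Parameters
    ----------
    data : DataFrame
        One row per subject (index = subject id), columns = indicators.
    standardize : bool
        Z-score the indicators before clustering (default).  The raw
        scale is also supported for sensitivity analyses.
    """

    def __init__(self, data: pd.DataFrame, standardize: bool = True):
        self.data = data
        self.standardize = standardize
        self.exog = (standardize_indicators(data) if standardize
                     else data.astype(float))

    def fit(self, k_range: range | list[int] | None = None,
            methods: tuple[str, ...] = METHODS,
            random_state: int = 0) -> "ClusteringResults":
        """Run every (method, k) pair and keep the best silhouette.

        Silhouette is computed with Euclidean distance for both methods
        so scores are comparable; ties prefer k-means, then smaller k.
        """
        n = len(self.exog)
        if k_range is None:
            k_range = range(2, min(8, n - 1) + 1)
        k_range = sorted(k_range)
        if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        X = self.exog.to_numpy()
        profiles: dict[str, dict[int, float]] = {m: {} for m in methods}
        best = None  # (score, method-preference, -k, labels, method, k)
        for method in methods:
            if method not in METHODS:
                raise ValueError(f"unknown clustering method {method!r}")
            for k in k_range:
                labels = _cluster_labels(X, method, k, random_state)
                if np.unique(labels).size < 2:
                    warnings.warn(f"{method} k={k}: degenerate single cluster")
                    profiles[method][k] = float("nan")
                    continue
                score = float(silhouette_score(X, labels))
                profiles[method][k] = score
                key = (score, -METHODS.index(method), -k)
                if best is None or key > best[0]:
                    best = (key, labels, method, k)
        if best is None:
            raise ValueError("no valid clustering configuration found")
        _, labels, method, k = best
        importances = rank_feature_importance(
            X, labels, feature_names=list(self.exog.columns),
            random_state=random_state)
        return ClusteringResults(
            model=self, method=method, k=k,
            labels=pd.Series(labels, index=self.data.index, name="group"),
            silhouette_by_k=profiles, importances=importances)


@dataclass
class ClusteringResults:
    """Selected grouping with full silhouette profiles and importances."""

    model: IndicatorClustering
    method: str
    k: int
    labels: pd.Series
    silhouette_by_k: dict[str, dict[int, float]]
    importances: pd.Series = field(repr=False)

    @property
    def silhouette(self) -> float:
        return self.silhouette_by_k[self.method][self.k]

    def group_members(self) -> dict[int, list]:
        return {g: list(idx) for g, idx in
                self.labels.groupby(self.labels).groups.items()}

    def summary(self) -> str:
        lines = ["Health-indicator clustering",
                 "=" * 27,
                 f"subjects: {len(self.labels)}",
                 f"selected: {self.method}, k={self.k} "
                 f"(silhouette {self.silhouette:.3f})",
                 "",
                 "silhouette by k:"]
        for method, prof in self.silhouette_by_k.items():
            row = "  ".join(f"k={k}:{v:.3f}" for k, v in sorted(prof.items()))
            lines.append(f"  {method:<9} {row}")
        lines.append("")
        lines.append("indicator importances (extra trees, sum 1):")
        for name, value in self.importances.items():
            lines.append(f"  {name:<14} {value:.3f}")
        sizes = self.labels.value_counts().sort_index()
        lines.append("")
        lines.append("group sizes: " +
                     ", ".join(f"{g}: {c}" for g, c in sizes.items()))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "silhouette": self.silhouette,
            "labels": {str(s): int(g) for s, g in self.labels.items()},
            "silhouette_by_k": {m: {int(k): v for k, v in prof.items()}
                                for m, prof in self.silhouette_by_k.items()},
            "importances": {str(n): float(v)
                            for n, v in self.importances.items()},
        }
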
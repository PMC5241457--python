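"""Distance analytics in eigenbehavior spaces.

All similarities are squared Euclidean distances between weight vectors
obtained by projecting mean-adjusted behaviors into an eigenbehavior
space: day-to-day distances in an individual's own space, subject-to-
subject distances in a group space, and the residual distance of a
subject's average behavior from a group subspace (how far their behavior
lies outside the group's routine).  The residuals per (space, group)
feed a leave-one-subject-out classifier that asks whether indicator-based
groups are recoverable from behavior alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .behavior import BehaviorMatrix
from .eigen import EigenBehavior, EigenBehaviorResults


def day_distance_matrix(matrix: BehaviorMatrix | np.ndarray,
                        k: int | None = None,
                        threshold: float = 0.9) -> np.ndarray:
    """Pairwise squared distances between days in the individual's space.

    Each day is projected onto the individual's k primary eigenbehaviors
    (default: the 90%-variability count) and the squared Euclidean
    distance between weight vectors is returned as a symmetric D x D
    matrix with zero diagonal.
    """
    res = EigenBehavior(matrix).fit()
    values = res.model.endog
    if res.rank == 0:
        return np.zeros((values.shape[0], values.shape[0]))
    if k is None:
        k = res.primary_count(threshold)
    if k > res.rank:
        raise ValueError(f"k={k} exceeds model rank {res.rank}")
    omegas = (values - res.psi) @ res.eigvecs[:, :k]
    return squareform(pdist(omegas, metric="sqeuclidean"))


def day_index_vector(dist: np.ndarray) -> np.ndarray:
    """For each day, the 1-based index of its most similar other day.

    Ties are broken towards the smallest index.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 days")
    masked = dist.copy()
    np.fill_diagonal(masked, np.inf)
    return np.argmin(masked, axis=1) + 1


def overlap_percentage(index_a: np.ndarray, index_b: np.ndarray) -> float:
    """Fraction of days whose most-similar day agrees across two spaces."""
    index_a = np.asarray(index_a)
    index_b = np.asarray(index_b)
    if index_a.shape != index_b.shape:
        raise ValueError("day index vectors must have equal length")
    return float(np.mean(index_a == index_b))


def individual_pair_distances(group_results: EigenBehaviorResults,
                              psis: np.ndarray,
                              k: int | None = None,
                              threshold: float = 0.9) -> np.ndarray:
    """Pairwise squared distances between subjects in a group space.

    Every subject's average behavior is projected into the given group
    eigenbehavior space; entry (i, j) is ||Omega_i - Omega_j||^2.
    """
    psis = np.atleast_2d(np.asarray(psis, dtype=float))
    if k is None:
        k = group_results.primary_count(threshold) if group_results.rank else 0
    if k == 0:
        return np.zeros((psis.shape[0], psis.shape[0]))
    omegas = (psis - group_results.psi) @ group_results.eigvecs[:, :k]
    return squareform(pdist(omegas, metric="sqeuclidean"))


def group_residual_distance(psi_subject: np.ndarray,
                            group_results: EigenBehaviorResults,
                            k: int | None = None,
                            threshold: float = 0.9) -> float:
    """Squared residual of a subject's behavior from a group subspace.

    phi = Psi_subject - Psi_group is projected onto the k leading group
    eigenbehaviors; the result is ||phi - phi_b||^2, zero iff the
    subject's mean-adjusted behavior lies inside the group subspace.
    """
    if group_results.rank == 0:
        phi = np.asarray(psi_subject, dtype=float) - group_results.psi
        return float(phi @ phi)
    if k is None:
        k = group_results.primary_count(threshold)
    return group_results.residual_norm2(psi_subject, k)


@dataclass
class MembershipResult:
    """Leave-one-subject-out group-membership classification report."""

    accuracies: dict[str, float]
    predictions: pd.DataFrame
    feature_names: list[str]

    def summary(self) -> str:
        lines = ["Group membership from behavior distances",
                 "=" * 40,
                 f"features: {', '.join(self.feature_names)}",
                 "LOSO accuracy:"]
        for name, acc in self.accuracies.items():
            lines.append(f"  {name:<14} {acc:.3f}")
        return "\n".join(lines)


def _fit_group_spaces(psis: pd.DataFrame, labels: pd.Series,
                      subjects: list) -> dict[int, EigenBehaviorResults]:
    spaces = {}
    for g in sorted(labels.unique()):
        members = [s for s in subjects if labels[s] == g]
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects "
                             "in a training fold")
        spaces[g] = EigenBehavior(psis.loc[members].to_numpy()).fit()
    return spaces


def membership_features(psis_by_space: dict[str, pd.DataFrame],
                        labels: pd.Series,
                        train_subjects: list,
                        threshold: float = 0.9) -> pd.DataFrame:
    """Residual-distance features epsilon^2 per (space, group) pair.

    Group eigenmodels are fit from the average behaviors of
    ``train_subjects`` only; features are computed for every subject in
    ``labels`` (2 spaces x n_groups columns).
    """
    columns = {}
    for space, psis in psis_by_space.items():
        spaces = _fit_group_spaces(psis, labels, train_subjects)
        for g, res in spaces.items():
            columns[f"{space}_g{g}"] = [
                group_residual_distance(psis.loc[s].to_numpy(), res,
                                        threshold=threshold)
                for s in labels.index]
    return pd.DataFrame(columns, index=labels.index)


def _classifiers(X_train: np.ndarray, y_train: np.ndarray,
                 random_state: int) -> dict:
    """Decision tree, random forest and rbf SVM with inner-CV grid search."""
    counts = np.bincount(y_train)
    inner = StratifiedKFold(n_splits=max(2, min(3, counts[counts > 0].min())))
    var = X_train.var()
    gamma_scale = 1.0 / (X_train.shape[1] * var) if var > 0 else 1.0
    return {
        "decision_tree": DecisionTreeClassifier(random_state=random_state),
        "random_forest": GridSearchCV(
            RandomForestClassifier(n_estimators=101, random_state=random_state),
            {"max_depth": [2, 3, 5, None]}, cv=inner),
        "svm": GridSearchCV(
            SVC(kernel="rbf"),
            {"C": [0.1, 1.0, 10.0],
             "gamma": [0.5 * gamma_scale, gamma_scale, 2.0 * gamma_scale]},
            cv=inner),
    }


def classify_membership(psis_by_space: dict[str, pd.DataFrame],
                        labels: pd.Series,
                        threshold: float = 0.9,
                        random_state: int = 0) -> MembershipResult:
    """Can behavior distances recover the indicator-based grouping?

    Leave-one-subject-out cross-validation: for each fold the group
    eigenmodels are refit excluding the held-out subject (no leakage of
    the test subject into the group spaces), residual-distance features
    are recomputed, and a decision tree, a 101-tree random forest and an
    rbf SVM (both tuned by grid search with inner CV on the training
    fold) predict the held-out subject's group.
    """
    subjects = list(labels.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups")
    y = labels.to_numpy()
    preds: dict[str, list] = {"decision_tree": [], "random_forest": [], "svm": []}
    feature_names: list[str] = []
    for i, held_out in enumerate(subjects):
        train = [s for s in subjects if s != held_out]
        feats = membership_features(psis_by_space, labels, train, threshold)
        feature_names = list(feats.columns)
        X_train = feats.loc[train].to_numpy()
        y_train = labels.loc[train].to_numpy()
        X_test = feats.loc[[held_out]].to_numpy()
        for name, clf in _classifiers(X_train, y_train, random_state).items():
            clf.fit(X_train, y_train)
            preds[name].append(clf.predict(X_test)[0])
    predictions = pd.DataFrame({"true": y, **preds}, index=subjects)
    accuracies = {name: float(np.mean(predictions[name] == predictions["true"]))
                  for name in preds}
    return MembershipResult(accuracies=accuracies, predictions=predictions,
                            feature_names=feature_names)
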
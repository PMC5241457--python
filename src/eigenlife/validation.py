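"""Permutation-null validation of indicator-based grouping.

If the grouping found on health indicators is reflected in behavior, the
within- and between-group behavior distances under the real grouping
should be extreme relative to the same statistics under random
re-groupings of identical sizes.  The null is built by shuffling subjects
across groups (100 shuffles by default), refitting the group
eigenbehavior spaces per shuffle, and recording the mean residual
distances d^{gg'}: d^{00} and d^{11} within groups, d^{01} and d^{10}
between groups (group-g subjects projected into group g'), per behavior
space.  An observed statistic lying outside the central 95% of its null
is evidence that the grouping is behaviorally meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .eigen import EigenBehavior
from .similarity import group_residual_distance


def shuffle_groups(labels: pd.Series | np.ndarray, n_shuffles: int = 100,
                   seed: int | np.random.Generator | None = None) -> list[np.ndarray]:
    """Random re-groupings preserving the number and sizes of groups.

    Each shuffle is a permutation of the label vector (sampling without
    replacement), so every group keeps exactly its original size.
    """
    values = np.asarray(labels)
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 groups to shuffle")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return [rng.permutation(values) for _ in range(n_shuffles)]


def group_mean_distances(psis_by_space: dict[str, pd.DataFrame],
                         labels: np.ndarray,
                         threshold: float = 0.9) -> dict[str, float]:
    """Mean residual distances d^{gg'} per space for one grouping.

    For each behavior space, group eigenmodels are fit from the member
    average behaviors; d^{gg'} is the mean over subjects of group g of
    their residual distance from the group-g' space.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    out: dict[str, float] = {}
    for space, psis in psis_by_space.items():
        values = psis.to_numpy()
        spaces = {}
        for g in groups:
            members = values[labels == g]
            if len(members) < 2:
                raise ValueError(f"group {g} has fewer than 2 members")
            spaces[g] = EigenBehavior(members).fit()
        for g in groups:
            member_rows = values[labels == g]
            for gp in groups:
                dists = [group_residual_distance(row, spaces[gp],
                                                 threshold=threshold)
                         for row in member_rows]
                out[f"{space}_d{g}{gp}"] = float(np.mean(dists))
    return out


@dataclass
class NullDistributions:
    """Observed group-distance statistics with their permutation nulls."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    n_shuffles: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": k, "observed": v,
                 **{f"null_{i}": x for i, x in enumerate(self.null[k])}}
                for k, v in self.observed.items()]
        return pd.DataFrame(rows)


def null_distance_distributions(psis_by_space: dict[str, pd.DataFrame],
                                labels: pd.Series | np.ndarray,
                                n_shuffles: int = 100,
                                seed: int | np.random.Generator | None = None,
                                threshold: float = 0.9) -> NullDistributions:
    """Observed d^{gg'} statistics and their 100-shuffle null distributions.

    The observed statistics and every null entry go through the same code
    path; group eigenspaces (and their primary dimensionality) are refit
    for every shuffled grouping.
    """
    labels = np.asarray(labels)
    observed = group_mean_distances(psis_by_space, labels, threshold)
    shuffles = shuffle_groups(labels, n_shuffles=n_shuffles, seed=seed)
    null: dict[str, list[float]] = {k: [] for k in observed}
    for shuffled in shuffles:
        stats = group_mean_distances(psis_by_space, shuffled, threshold)
        for k, v in stats.items():
            null[k].append(v)
    return NullDistributions(
        observed=observed,
        null={k: np.asarray(v) for k, v in null.items()},
        n_shuffles=n_shuffles)


def compare_observed_to_null(nd: NullDistributions,
                             bulk: tuple[float, float] = (2.5, 97.5)
                             ) -> pd.DataFrame:
    """Empirical percentile of each observed statistic within its null.

    A statistic is flagged ``outside_bulk`` when it falls outside the
    central interval (default [2.5, 97.5]) of the null.  The tail
    probabilities use the add-one Monte-Carlo convention
    p = (1 + #{null at least as extreme}) / (1 + n_shuffles), which
    keeps the flag at its nominal level for a finite number of shuffles.
    """
    if nd.n_shuffles < 20:
        raise ValueError("need at least 20 shuffles for a meaningful bulk")
    lo_level = bulk[0] / 100.0
    hi_level = (100.0 - bulk[1]) / 100.0
    rows = []
    for stat, obs in nd.observed.items():
        null = nd.null[stat]
        pct = float(percentileofscore(null, obs, kind="mean"))
        p_low = (1 + np.sum(null <= obs)) / (1 + len(null))
        p_high = (1 + np.sum(null >= obs)) / (1 + len(null))
        rows.append({"statistic": stat, "observed": obs,
                     "percentile": pct,
                     "outside_bulk": bool(p_low <= lo_level
                                          or p_high <= hi_level)})
    return pd.DataFrame(rows).set_index("statistic")
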